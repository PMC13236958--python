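"""Configuration, six-step orchestration and the study-batch simulator.

An audit is declared in a YAML or JSON config (see
``bayes_audit/data/bargh1996.yaml`` for the packaged walking-speed
example) and executed by :func:`run_audit`, which runs the steps in
order: the claim block is Step 1; priors (Step 2) are updated (Step 4)
by the evidence translated or stipulated in Step 3; sensitivity (Step 5)
and the proportionality synthesis (Step 6) complete the report.

The simulator draws batches of noncentral-t study summaries for
calibration experiments: under a true standardized effect d the t
statistic has noncentrality d * sqrt(effective N), and under d = 0 the
universal bound Pr(BF10 >= c | H0) <= 1/c can be checked empirically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .belief_core import (
    BayesFactorEvidence,
    BeliefRole,
    BfMethod,
    ProbabilityOfTruth,
    Sidedness,
    combine_evidence,
    update_belief,
)
from .evidence_translation import (
    BfMethodSpec,
    Direction,
    StudySummary,
    bf_from_reported,
)
from .exceptions import ConfigurationError, ContractError, DomainError
from .proportional_synthesis import (
    AuditReport,
    ClaimStatement,
    ClaimStrength,
    classify_belief,
    proportionality_verdict,
    suggest_language,
)
from .reverse_inference import required_prior
from .sensitivity_analysis import (
    DEFAULT_REASONABLE_BAND,
    curve_points,
    posterior_grid,
    stability_summary,
)

__all__ = [
    "AuditConfig",
    "SimulatedStudyBatch",
    "load_config",
    "run_audit",
    "simulate_studies",
    "calibration_check",
    "packaged_config_path",
]

logger = logging.getLogger("bayes_audit")


# -- configuration schema ------------------------------------------------


class ClaimBlock(BaseModel):
    text: str
    strength: ClaimStrength
    scope_note: str = ""


class PriorSpec(BaseModel):
    value: float = Field(gt=0.0, lt=1.0)
    label: str = ""


class StudyRow(BaseModel):
    label: str = ""
    t: float
    df: int = Field(ge=1)
    n1: int = Field(ge=1)
    n2: int | None = Field(default=None, ge=1)
    p: float | None = Field(default=None, gt=0.0, lt=1.0)
    d: float | None = None
    direction: Direction = Direction.UNDIRECTED


class MethodBlock(BaseModel):
    method: BfMethod = BfMethod.JZS
    prior_scale: float = Field(default=math.sqrt(2.0) / 2.0, gt=0.0)
    sided: Sidedness = Sidedness.TWO_SIDED
    quadrature_tol: float = Field(default=1e-8, gt=0.0, le=1e-4)


class EvidenceBlock(BaseModel):
    stipulated: list[float] | None = None
    studies: list[StudyRow] | None = None
    method: MethodBlock = MethodBlock()
    combine: bool = False

    @model_validator(mode="after")
    def _at_least_one_source(self) -> "EvidenceBlock":
        if not self.stipulated and not self.studies:
            raise ValueError("evidence requires 'stipulated' values or 'studies' rows")
        if self.stipulated is not None and any(b <= 0 for b in self.stipulated):
            raise ValueError("stipulated Bayes factors must be positive")
        return self


class SensitivityBlock(BaseModel):
    bfs: list[float] = [1.0, 3.0, 10.0]
    reasonable_band: tuple[float, float] = DEFAULT_REASONABLE_BAND
    threshold: float = Field(default=0.5, gt=0.0, lt=1.0)
    grid_points: int = Field(default=99, ge=2)


class OutputBlock(BaseModel):
    formats: list[str] = ["markdown", "json"]
    plot: bool = False


class AuditConfig(BaseModel):
    """Validated audit declaration (Step 1 is the claim block itself)."""

    claim: ClaimBlock
    priors: list[PriorSpec] = Field(min_length=1)
    evidence: EvidenceBlock
    sensitivity: SensitivityBlock = SensitivityBlock()
    output: OutputBlock = OutputBlock()
    seed: int = 0


def packaged_config_path(name: str = "bargh1996") -> Path:
    """Path of a config shipped with the package (the walking-speed case)."""
    path = Path(__file__).parent / "data" / f"{name}.yaml"
    if not path.exists():
        raise ConfigurationError(f"no packaged config named {name!r}")
    return path


def load_config(path: str | Path) -> AuditConfig:
    """Load and validate an audit config from a YAML or JSON file.

    All schema violations are collected and reported at once; defaults
    filled in by the schema are logged at info level.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping; got {type(raw).__name__}")
    try:
        cfg = AuditConfig.model_validate(raw)
    except ValidationError as exc:
        failures = "; ".join(
            f"{'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid audit config ({path.name}): {failures}") from exc
    for block in ("sensitivity", "output"):
        if block not in raw:
            logger.info("config %s: block %r absent, defaults applied", path.name, block)
    return cfg


# -- orchestration -------------------------------------------------------


def _translate_evidence(
    cfg: AuditConfig,
) -> tuple[list[BayesFactorEvidence], list[BayesFactorEvidence], list[str]]:
    """Returns (all evidence, evidence used for updating, notes).

    Stipulated Bayes factors take reproduction precedence: when present,
    only they drive the update; study-row translations are still computed
    and listed so the report can show what recomputation would give.
    """
    evidence: list[BayesFactorEvidence] = []
    updating: list[BayesFactorEvidence] = []
    notes: list[str] = []
    block = cfg.evidence
    if block.stipulated:
        for bf in block.stipulated:
            evidence.append(
                BayesFactorEvidence(
                    bf, method=BfMethod.STIPULATED, source_note="stipulated in config"
                )
            )
        updating = list(evidence)
        if block.studies:
            logger.info(
                "both stipulated BFs and study rows supplied; stipulated values "
                "take reproduction precedence"
            )
            notes.append(
                "stipulated Bayes factors take precedence over study-row translation"
            )
    if block.studies:
        spec = BfMethodSpec(
            method=block.method.method,
            prior_scale=block.method.prior_scale,
            sided=block.method.sided,
            quadrature_tol=block.method.quadrature_tol,
        )
        for row in block.studies:
            summary = StudySummary(
                t_value=row.t,
                df=row.df,
                n1=row.n1,
                n2=row.n2,
                p_value=row.p,
                effect_d=row.d,
                direction=row.direction,
                label=row.label,
            )
            evidence.append(bf_from_reported(summary, spec))
    if not updating:
        updating = [e for e in evidence if e.method is not BfMethod.STIPULATED]
    return evidence, updating, notes


def run_audit(cfg: AuditConfig) -> AuditReport:
    """Execute the six audit steps on a validated config.

    Deterministic given the config.  Posteriors are listed in ascending
    order of prior; the belief band (and hence the verdict) is taken at
    the most optimistic prior, so a claim judged over-stated is
    over-stated even on its most charitable reading.
    """

    def step(name: str):
        logger.info("audit step: %s", name)

    step("2: priors")
    priors = sorted(
        (
            ProbabilityOfTruth(p.value, BeliefRole.PRIOR, p.label)
            for p in cfg.priors
        ),
        key=lambda p: p.value,
    )

    step("3: evidence translation")
    try:
        evidence, updating, notes = _translate_evidence(cfg)
    except (DomainError, ConfigurationError) as exc:
        raise type(exc)(f"step 3 (evidence translation): {exc}") from exc
    if cfg.evidence.combine:
        effective = combine_evidence(updating)
        notes.append(
            "evidence combined by naive independence product; the cumulative "
            "impact depends on the aggregation rule"
        )
    else:
        effective = updating[0]
        if len(updating) > 1:
            notes.append(
                "multiple evidence sources present; updating used the first "
                "(combination disabled)"
            )

    step("4: posterior updating")
    posteriors = tuple(update_belief(p, effective) for p in priors)

    step("5: sensitivity")
    sens = cfg.sensitivity
    bf_rows = sorted(set(sens.bfs) | {effective.bf10})
    grid = posterior_grid(
        [float(p) for p in np.linspace(0.01, 0.99, sens.grid_points)], bf_rows
    )
    stability = stability_summary(
        grid,
        bf_rows.index(effective.bf10),
        sens.threshold,
        tuple(sens.reasonable_band),
    )
    reverse = required_prior(effective, sens.threshold)

    step("6: proportional synthesis")
    claim = ClaimStatement(
        text=cfg.claim.text, strength=cfg.claim.strength, scope_note=cfg.claim.scope_note
    )
    belief = classify_belief(max(p.value for p in posteriors))
    verdict = proportionality_verdict(claim, belief)
    report = AuditReport(
        claim=claim,
        priors_used=tuple(priors),
        evidence=tuple(evidence),
        effective_evidence=effective,
        posteriors=posteriors,
        stability=stability,
        reverse=reverse,
        belief=belief,
        verdict=verdict,
        suggested_language="",
        grid=grid,
        warnings=tuple(notes),
    )
    # suggested language needs the assembled report; rebuild with it
    object.__setattr__(report, "suggested_language", suggest_language(report))
    return report


# -- simulation ----------------------------------------------------------


@dataclass(frozen=True)
class SimulatedStudyBatch:
    """A reproducible batch of simulated t-test summaries.

    Regenerating with the same seed reproduces the summaries
    bit-for-bit; ``true_effect_d = 0`` yields central-t draws.
    """

    n_studies: int
    true_effect_d: float
    per_study_n1: int
    per_study_n2: int | None
    seed: int
    summaries: tuple[StudySummary, ...]


def simulate_studies(
    n_studies: int,
    true_effect_d: float,
    n1: int,
    n2: int | None = None,
    seed: int = 0,
) -> SimulatedStudyBatch:
    """Draw study summaries with t ~ noncentral-t(df, d * sqrt(N_eff)).

    The draw is constructed from its definition, t = (Z + ncp) /
    sqrt(V/df) with Z standard normal and V chi-squared, so that
    reproducibility depends only on the named generator and seed.
    """
    if n_studies < 1 or n1 < 1 or (n2 is not None and n2 < 1):
        raise DomainError(
            f"sizes must be positive; got n_studies={n_studies}, n1={n1}, n2={n2}"
        )
    if n2 is not None:
        df = n1 + n2 - 2
        n_eff = n1 * n2 / (n1 + n2)
    else:
        df = n1 - 1
        n_eff = float(n1)
    if df < 1:
        raise DomainError(f"design has no residual degrees of freedom (df={df})")
    rng = np.random.default_rng(seed)
    ncp = true_effect_d * math.sqrt(n_eff)
    z = rng.standard_normal(n_studies)
    v = rng.chisquare(df, n_studies)
    t = (z + ncp) / np.sqrt(v / df)
    from scipy import stats

    p = 2.0 * stats.t.sf(np.abs(t), df)
    summaries = tuple(
        StudySummary(
            t_value=float(t[i]),
            df=df,
            n1=n1,
            n2=n2,
            p_value=float(min(max(p[i], 1e-300), 1.0 - 1e-16)),
            direction=Direction.UNDIRECTED,
            label=f"sim-{i:05d}",
        )
        for i in range(n_studies)
    )
    return SimulatedStudyBatch(
        n_studies=n_studies,
        true_effect_d=true_effect_d,
        per_study_n1=n1,
        per_study_n2=n2,
        seed=seed,
        summaries=summaries,
    )


def batch_to_frame(batch: SimulatedStudyBatch) -> pd.DataFrame:
    """Tabular view of a simulated batch (label, t, df, n1, n2, p)."""
    return pd.DataFrame(
        {
            "label": [s.label for s in batch.summaries],
            "t": [s.t_value for s in batch.summaries],
            "df": [s.df for s in batch.summaries],
            "n1": [s.n1 for s in batch.summaries],
            "n2": [s.n2 for s in batch.summaries],
            "p": [s.p_value for s in batch.summaries],
        }
    )


def calibration_check(
    batch: SimulatedStudyBatch,
    spec: BfMethodSpec | None = None,
    c_values: tuple[float, ...] = (3.0, 10.0),
    require_null: bool = True,
) -> pd.DataFrame:
    """Empirical exceedance rates Pr(BF10 >= c) over a simulated batch.

    With ``require_null`` (the default) the batch must have been drawn
    under d = 0, where the Markov inequality on marginal likelihood
    ratios bounds the exceedance by 1/c; passing a nonnull batch is a
    contract violation.  Set ``require_null=False`` for power
    comparisons under a true effect.

    Returns a frame with columns c, n, n_exceed, rate, se, markov_bound.
    """
    if require_null and batch.true_effect_d != 0.0:
        raise ContractError(
            "the Markov-bound check requires a null batch (true_effect_d = 0); "
            "pass require_null=False for power comparisons"
        )
    spec = spec or BfMethodSpec()
    bfs = np.array([bf_from_reported(s, spec).bf10 for s in batch.summaries])
    rows = []
    n = len(bfs)
    for c in c_values:
        exceed = int(np.sum(bfs >= c))
        rate = exceed / n
        rows.append(
            {
                "c": c,
                "n": n,
                "n_exceed": exceed,
                "rate": rate,
                "se": math.sqrt(rate * (1.0 - rate) / n),
                "markov_bound": 1.0 / c,
            }
        )
    return pd.DataFrame(rows)
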
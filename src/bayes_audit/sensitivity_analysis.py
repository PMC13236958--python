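"""Sensitivity of posterior belief to prior plausibility.

A claim whose posterior support survives only under optimistic priors
lacks epistemic stability.  This module evaluates the posterior surface
over a grid of priors and Bayes factors, locates the break-even prior at
which the posterior reaches a threshold, and summarizes which portion of
a "reasonable" prior band meets that threshold.

The break-even prior at threshold 0.5 has the closed form 1/(1 + BF10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .belief_core import BayesFactorEvidence, ProbabilityOfTruth, update_belief
from .exceptions import ConfigurationError, DomainError
from .reverse_inference import required_prior

__all__ = [
    "SensitivityGrid",
    "StabilityReport",
    "posterior_grid",
    "breakeven_prior",
    "stability_summary",
    "curve_points",
    "plot_curves",
]

#: Prior band the audit treats as "reasonable" by default (skeptical to
#: optimistic); configurable wherever it is consumed.
DEFAULT_REASONABLE_BAND: tuple[float, float] = (0.05, 0.20)


@dataclass(frozen=True)
class SensitivityGrid:
    """Posterior probabilities over priors (columns) x Bayes factors (rows)."""

    priors: tuple[float, ...]
    bfs: tuple[float, ...]
    posteriors: np.ndarray  # shape (len(bfs), len(priors))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view with columns prior, bf, posterior."""
        records = [
            {"prior": p, "bf": b, "posterior": self.posteriors[i, j]}
            for i, b in enumerate(self.bfs)
            for j, p in enumerate(self.priors)
        ]
        return pd.DataFrame.from_records(records, columns=["prior", "bf", "posterior"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def row(self, bf_index: int) -> np.ndarray:
        return self.posteriors[bf_index]


@dataclass(frozen=True)
class StabilityReport:
    """Epistemic-stability summary of one Bayes-factor row of a grid.

    ``prior_range_meeting_threshold`` is the (min, max) of the *grid
    points* whose posterior meets the threshold, or None when no point
    does; the analytic break-even prior is reported separately so no
    interpolation between grid points is implied.  ``stable`` is true iff
    the meeting range covers the reasonable prior band entirely — a
    documented convention, since stability has no canonical numeric
    definition.
    """

    threshold: float
    breakeven_prior: float
    prior_range_meeting_threshold: tuple[float, float] | None
    stable: bool
    reasonable_band: tuple[float, float] = DEFAULT_REASONABLE_BAND


def posterior_grid(
    priors: list[float], bfs: list[float]
) -> SensitivityGrid:
    """Evaluate the posterior for every (prior, Bayes factor) pair.

    Each cell is computed by the scalar belief update, so matrix assembly
    introduces no drift; rows are strictly increasing in the prior and
    columns in the Bayes factor.
    """
    if not priors or not bfs:
        raise ConfigurationError("priors and bfs must both be nonempty")
    for j, p in enumerate(priors):
        if not (0.0 < p < 1.0):
            raise DomainError(f"prior at index {j} must lie in (0, 1); got {p!r}")
    for i, b in enumerate(bfs):
        if not b > 0.0:
            raise DomainError(f"Bayes factor at index {i} must be positive; got {b!r}")
    matrix = np.empty((len(bfs), len(priors)))
    for i, b in enumerate(bfs):
        ev = BayesFactorEvidence(b)
        for j, p in enumerate(priors):
            matrix[i, j] = update_belief(ProbabilityOfTruth(p), ev).value
    return SensitivityGrid(tuple(float(p) for p in priors), tuple(float(b) for b in bfs), matrix)


def breakeven_prior(
    ev: BayesFactorEvidence | float, threshold: float = 0.5
) -> float:
    """Prior at which the posterior reaches ``threshold``; 1/(1+BF) at 0.5."""
    if not isinstance(ev, BayesFactorEvidence):
        ev = BayesFactorEvidence(ev)
    if not (0.0 < threshold < 1.0):
        raise DomainError(f"threshold must lie in (0, 1); got {threshold!r}")
    return required_prior(ev, threshold).solved_value


def stability_summary(
    grid: SensitivityGrid,
    bf_index: int,
    threshold: float,
    reasonable_band: tuple[float, float] = DEFAULT_REASONABLE_BAND,
) -> StabilityReport:
    """Summarize how much of the prior range supports the claim.

    Reports the sub-range of the supplied priors whose posteriors meet
    ``threshold`` under the Bayes factor at ``bf_index``, the analytic
    break-even prior, and whether the meeting range covers the reasonable
    band entirely.
    """
    if not (0 <= bf_index < len(grid.bfs)):
        raise ConfigurationError(
            f"bf_index {bf_index} out of range for {len(grid.bfs)} Bayes factors"
        )
    if not (0.0 < threshold < 1.0):
        raise DomainError(f"threshold must lie in (0, 1); got {threshold!r}")
    bf = grid.bfs[bf_index]
    meeting = [p for p, post in zip(grid.priors, grid.row(bf_index)) if post >= threshold]
    prior_range = (min(meeting), max(meeting)) if meeting else None
    lo, hi = reasonable_band
    stable = bool(
        prior_range is not None and prior_range[0] <= lo and prior_range[1] >= hi
    )
    return StabilityReport(
        threshold=float(threshold),
        breakeven_prior=breakeven_prior(bf, threshold),
        prior_range_meeting_threshold=prior_range,
        stable=stable,
        reasonable_band=(float(lo), float(hi)),
    )


def curve_points(
    ev: BayesFactorEvidence | float, n_points: int = 99
) -> SensitivityGrid:
    """Posterior-vs-prior curve on evenly spaced priors over [0.01, 0.99].

    The default 99 points give a 0.01 step, covering the unit interval
    without boundary degeneracy.  Used by the curve plotter.
    """
    if n_points < 2:
        raise ConfigurationError(f"n_points must be >= 2; got {n_points!r}")
    bf = ev.bf10 if isinstance(ev, BayesFactorEvidence) else float(ev)
    priors = np.linspace(0.01, 0.99, n_points)
    return posterior_grid([float(p) for p in priors], [bf])


def plot_curves(
    bfs: list[float],
    path,
    n_points: int = 99,
) -> None:
    """Write a posterior-vs-prior figure: one curve per Bayes factor plus
    the dashed identity diagonal (the BF = 1 no-update reference)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xs = np.linspace(0.01, 0.99, n_points)
    for bf in bfs:
        grid = curve_points(bf, n_points)
        ax.plot(xs, grid.row(0), label=f"BF$_{{10}}$ = {bf:g}")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", label="identity")
    ax.set_xlabel("prior probability $p_0$")
    ax.set_ylabel("posterior probability $p_{post}$")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
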
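"""Probability/odds algebra and the odds-form Bayesian updating engine.

The quantity being updated is the probability that a scientific claim is
*true* — a prior model probability, not a parameter distribution.  Updating
is the odds form of Bayes' theorem:

    odds(prior)     = p0 / (1 - p0)
    odds(posterior) = BF10 * odds(prior)
    p_post          = odds(posterior) / (1 + odds(posterior))

where BF10 = P(D | H1) / P(D | H0) is the Bayes factor quantifying the
evidential shift carried by the data, independent of the prior.

Probabilities are kept strictly inside the open interval (0, 1): a dogmatic
prior of exactly 0 or 1 cannot be moved by any finite Bayes factor, and
silently passing one through would mask a user error, so construction of
such values raises :class:`~bayes_audit.exceptions.DomainError`.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .exceptions import DomainError

__all__ = [
    "BeliefRole",
    "BfMethod",
    "Sidedness",
    "ProbabilityOfTruth",
    "OddsValue",
    "BayesFactorEvidence",
    "prob_to_odds",
    "odds_to_prob",
    "update_belief",
    "combine_evidence",
    "sequential_update",
]


class BeliefRole(str, enum.Enum):
    """Whether a probability of truth is held before or after the evidence."""

    PRIOR = "prior"
    POSTERIOR = "posterior"


class BfMethod(str, enum.Enum):
    """Provenance of a Bayes factor.

    ``stipulated`` marks a value taken as given from a published report
    (used to reproduce printed audits exactly) rather than recomputed.
    """

    JZS = "jzs"
    BIC = "bic"
    MIN_BOUND = "min_bound"
    STIPULATED = "stipulated"


class Sidedness(str, enum.Enum):
    TWO_SIDED = "two_sided"
    ONE_SIDED = "one_sided"


@dataclass(frozen=True)
class ProbabilityOfTruth:
    """A degree of belief that a claim is true, in the open interval (0, 1).

    Parameters
    ----------
    value
        The probability.  Boundary values 0 and 1 are rejected: they encode
        dogmatic belief that no evidence can update.
    role
        Whether this belief is held before (``prior``) or after
        (``posterior``) incorporating the evidence under audit.
    label
        Optional free-text tag, e.g. ``"skeptical"`` or ``"optimistic"``.
    """

    value: float
    role: BeliefRole = BeliefRole.PRIOR
    label: str = ""

    def __post_init__(self) -> None:
        v = self.value
        if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 < v < 1.0):
            raise DomainError(
                f"probability of truth must lie strictly inside (0, 1); got {v!r}"
            )
        object.__setattr__(self, "value", float(v))
        object.__setattr__(self, "role", BeliefRole(self.role))

    def as_posterior(self, value: float | None = None) -> "ProbabilityOfTruth":
        return replace(
            self,
            value=self.value if value is None else value,
            role=BeliefRole.POSTERIOR,
        )


@dataclass(frozen=True)
class OddsValue:
    """Odds in favor of the claim; 1 corresponds exactly to probability 0.5."""

    value: float

    def __post_init__(self) -> None:
        v = self.value
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0.0):
            raise DomainError(f"odds must be a finite nonnegative number; got {v!r}")
        object.__setattr__(self, "value", float(v))


@dataclass(frozen=True)
class BayesFactorEvidence:
    """A Bayes factor BF10 = P(D|H1)/P(D|H0) with its provenance.

    Parameters
    ----------
    bf10
        Positive finite Bayes factor in favor of the claim hypothesis.
    method
        How the value was obtained (``jzs``, ``bic``, ``min_bound``) or
        ``stipulated`` when carried over from a published report.
    sided
        Whether the alternative hypothesis is two-sided or restricted to
        the predicted direction.
    source_note
        Free-text provenance (study label, combination rule, ...).
    caveats
        Machine-readable caveat flags, e.g. ``naive_independence_product``.
    """

    bf10: float
    method: BfMethod = BfMethod.STIPULATED
    sided: Sidedness = Sidedness.TWO_SIDED
    source_note: str = ""
    caveats: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        v = self.bf10
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0.0):
            raise DomainError(f"BF10 must be a positive finite number; got {v!r}")
        object.__setattr__(self, "bf10", float(v))
        object.__setattr__(self, "method", BfMethod(self.method))
        object.__setattr__(self, "sided", Sidedness(self.sided))
        object.__setattr__(self, "caveats", tuple(self.caveats))


def prob_to_odds(p: ProbabilityOfTruth | float) -> OddsValue:
    """Convert a probability of truth to odds p/(1-p).

    Strictly increasing on (0, 1); the open-interval domain guarantees
    finite odds.
    """
    value = p.value if isinstance(p, ProbabilityOfTruth) else float(p)
    if not (0.0 < value < 1.0):
        raise DomainError(
            f"probability must lie strictly inside (0, 1) to form odds; got {value!r}"
        )
    return OddsValue(value / (1.0 - value))


def odds_to_prob(
    o: OddsValue | float, role: BeliefRole = BeliefRole.POSTERIOR, label: str = ""
) -> ProbabilityOfTruth:
    """Convert odds back to a probability odds/(1+odds).

    Exact inverse of :func:`prob_to_odds` on (0, 1).  Odds of 0 or values
    whose probability rounds to 1.0 in double precision are nudged to the
    nearest representable point inside the open interval so the result
    remains a valid :class:`ProbabilityOfTruth`.
    """
    value = o.value if isinstance(o, OddsValue) else float(o)
    if not (math.isfinite(value) and value >= 0.0):
        raise DomainError(f"odds must be finite and nonnegative; got {value!r}")
    p = value / (1.0 + value)
    # numerical guard: keep the open interval under extreme odds
    if p <= 0.0:
        p = math.nextafter(0.0, 1.0)
    elif p >= 1.0:
        p = math.nextafter(1.0, 0.0)
    return ProbabilityOfTruth(p, role=role, label=label)


def update_belief(
    prior: ProbabilityOfTruth, ev: BayesFactorEvidence
) -> ProbabilityOfTruth:
    """Update a prior probability of truth by a Bayes factor.

    Implements posterior odds = BF10 x prior odds, then converts back to a
    probability.  The result is strictly increasing in both the prior and
    the Bayes factor.  BF10 = 1 returns the prior bit-for-bit (weak
    evidence produces no change in belief); the shortcut keeps the
    identity exact instead of within a rounding error of the odds
    round-trip.
    """
    if ev.bf10 == 1.0:
        return prior.as_posterior()
    posterior_odds = ev.bf10 * prob_to_odds(prior).value
    return odds_to_prob(posterior_odds, role=BeliefRole.POSTERIOR, label=prior.label)


def combine_evidence(
    evs: Iterable[BayesFactorEvidence],
) -> BayesFactorEvidence:
    """Combine Bayes factors from independent studies by their product.

    The product rule is exact only when the studies are independent and
    each BF is computed against the same pair of hypotheses; the cumulative
    evidential impact genuinely depends on how aggregation is performed, so
    the result always carries the ``naive_independence_product`` caveat
    flag.  An empty list yields the evidentially inert identity BF10 = 1,
    with a warning.
    """
    evs = list(evs)
    if not evs:
        warnings.warn(
            "combining an empty evidence list: returning identity BF10 = 1",
            stacklevel=2,
        )
        return BayesFactorEvidence(
            1.0,
            method=BfMethod.STIPULATED,
            source_note="empty evidence list; identity Bayes factor",
            caveats=("empty_evidence",),
        )
    product = 1.0
    for ev in evs:
        if not (math.isfinite(ev.bf10) and ev.bf10 > 0.0):
            raise DomainError(f"cannot combine nonpositive BF10 {ev.bf10!r}")
        product *= ev.bf10
    return BayesFactorEvidence(
        product,
        method=BfMethod.STIPULATED,
        source_note=(
            f"product of {len(evs)} Bayes factors under a naive independence "
            "assumption; aggregation-dependent"
        ),
        caveats=("naive_independence_product",),
    )


def sequential_update(
    prior: ProbabilityOfTruth, evs: Sequence[BayesFactorEvidence]
) -> ProbabilityOfTruth:
    """Fold :func:`update_belief` over a sequence of Bayes factors.

    Algebraically identical to a single update with the product of the
    factors, and therefore invariant to the ordering of the evidence.
    """
    belief = prior
    for ev in evs:
        belief = update_belief(belief, ev)
    return belief.as_posterior()
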
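"""Reverse-Bayes solvers.

Instead of asking what posterior follows from a prior and the evidence,
these invert the odds-form update: what prior would make the observed
result reach a target level of belief (:func:`required_prior`), or how
much evidence a given prior would need (:func:`required_bf`)?  Both are
exact closed forms — the odds algebra is analytically invertible, so no
root-finding or tolerance knobs are involved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .belief_core import BayesFactorEvidence, ProbabilityOfTruth, prob_to_odds

__all__ = ["ReverseSolveResult", "required_prior", "required_bf"]


@dataclass(frozen=True)
class ReverseSolveResult:
    """Result of a reverse-Bayes solve.

    ``solved_value`` is a prior probability (for :func:`required_prior`)
    or a Bayes factor (for :func:`required_bf`); ``fixed_input`` echoes
    the quantity held fixed during the solve.
    """

    solved_value: float
    target_posterior: float
    fixed_input: dict[str, float]
    interpretation: str


def required_prior(
    ev: BayesFactorEvidence, target: ProbabilityOfTruth | float
) -> ReverseSolveResult:
    """Prior probability needed for the evidence to reach a target posterior.

    Closed form p0 = q / (q + BF10 * (1 - q)) with q the target; exact
    inverse of the belief update in its prior argument.  With BF10 = 1 the
    required prior equals the target (no evidence, belief cannot move).
    """
    q = target.value if isinstance(target, ProbabilityOfTruth) else float(target)
    prob_to_odds(q)  # domain check: q strictly inside (0, 1)
    p0 = q / (q + ev.bf10 * (1.0 - q))
    comparator = "more likely than not" if q == 0.5 else f"at least {q:g} probable"
    return ReverseSolveResult(
        solved_value=p0,
        target_posterior=q,
        fixed_input={"bf10": ev.bf10},
        interpretation=(
            f"a reader must hold a prior of at least {p0:.4g} to find this "
            f"claim {comparator} given BF10 = {ev.bf10:g}"
        ),
    )


def required_bf(
    prior: ProbabilityOfTruth | float, target: ProbabilityOfTruth | float
) -> ReverseSolveResult:
    """Bayes factor needed to move a given prior to a target posterior.

    Closed form BF = odds(target) / odds(prior); exact inverse of the
    belief update in its evidence argument.
    """
    p0 = prior.value if isinstance(prior, ProbabilityOfTruth) else float(prior)
    q = target.value if isinstance(target, ProbabilityOfTruth) else float(target)
    bf = prob_to_odds(q).value / prob_to_odds(p0).value
    return ReverseSolveResult(
        solved_value=bf,
        target_posterior=q,
        fixed_input={"prior": p0},
        interpretation=(
            f"evidence of BF10 = {bf:.4g} is needed to move a prior of "
            f"{p0:g} to a posterior of {q:g}"
        ),
    )
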
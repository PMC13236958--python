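# Methods

## Belief updating

The audited quantity is a prior *model* probability — the probability
p0 that the claim is true — not a prior distribution over an effect
size. Updating is the odds form of Bayes' theorem: posterior odds are
the prior odds p0/(1-p0) multiplied by the Bayes factor BF10, and the
posterior probability is odds/(1+odds). Probabilities are restricted to
the open interval (0, 1): a dogmatic 0 or 1 cannot be updated, and the
package treats such inputs as user error rather than passing degenerate
posteriors through. Posteriors are carried at full double precision
internally; rendered reports round probabilities to 2 decimals and
Bayes factors to 3 significant figures.

Two deliberate numerical choices in the updater:

- BF10 = 1 short-circuits to return the prior bit-for-bit, keeping the
  "no evidence, no belief change" identity exact rather than within a
  rounding error of the odds round-trip.
- Posteriors that would round to exactly 0.0 or 1.0 in double precision
  (only reachable with astronomically large or small Bayes factors) are
  nudged to the nearest representable point inside (0, 1).

Evidence from several studies can be combined by the product of their
Bayes factors. This is exact only under independence and shared
hypotheses, and the right aggregation is genuinely context-dependent,
so combination is off by default and every combined value carries a
machine-readable `naive_independence_product` caveat. An empty evidence
list combines to the identity BF10 = 1 with a warning.

## Bayes factors from reported statistics

Three translation routes are implemented, because a published "BF ≈ x"
rarely pins down a recipe:

- **JZS** (default): Cauchy(0, r) prior on the standardized effect
  size, Jeffreys prior on the variance. Writing the Cauchy as an
  inverse-gamma scale mixture of normals reduces the marginal
  likelihood under H1 to a one-dimensional integral over the mixing
  variance g; the integrand uses the t-density ratio at
  (1 + N g r^2) and the InvGamma(1/2, 1/2) weight. The integral is
  evaluated by adaptive quadrature after the change of variables
  u = g/(1+g) onto (0, 1), relative tolerance 1e-8; failure to converge
  raises a numerical error carrying the achieved tolerance rather than
  silently falling back. Default scale r = sqrt(2)/2 (the prevailing
  software default); r = 1 is available by configuration. Effective
  sample size is n for one-sample and n1 n2/(n1+n2) for two-sample
  designs.
- **BIC / unit-information**: BF01 ≈ sqrt(N_tot) (1 + t^2/df)^(-N_tot/2)
  with N_tot the total observation count, computed in logs to avoid
  overflow, returned as its reciprocal. Cheap, deterministic, and
  deliberately conservative at large N.
- **Minimum-BF bound**: -1/(e p ln p) for p < 1/e, else 1. An upper
  bound on the evidence any p-value can carry against the null over a
  wide class of alternatives; reports flag it as a bound, not an
  estimate.

For a directional claim, the one-sided adjustment multiplies the
two-sided Bayes factor by twice the posterior mass of the predicted
effect sign, computed by quadrature of the noncentral-t likelihood
against the Cauchy prior over each half-line. At t = 0 the posterior is
symmetric and the adjustment is a no-op; a correct strong prediction
approaches a doubling; a wrong-sign prediction is penalized.

When a report supplies both t and p and they disagree by more than 0.01
in two-sided p, a warning is issued and the t value wins (t determines
the likelihood; the p is only a cross-check).

The packaged walking-speed case carries its Bayes factor as
*stipulated* at the published value 3 rather than recomputing it: the
recomputed routes give 1.49 (JZS two-sided), 1.35 (BIC), 2.46 (minimum
bound) and ≈ 2.9 (JZS one-sided), so no default recipe reproduces the
printed value and the honest treatment is to carry it with explicit
`stipulated` provenance while reporting the recomputed spread alongside.

## Reverse-Bayes

Both solvers are exact closed-form inversions of the odds update —
p0 = q/(q + BF(1-q)) for the required prior and BF = odds(q)/odds(p0)
for the required evidence — avoiding root-finding and its tolerance
knobs. Results echo their fixed inputs and carry a one-line
interpretation for report assembly; tests verify the round trip through
the forward update to 1e-10.

## Sensitivity and stability

The posterior grid evaluates every (prior, BF) cell with the same
scalar update used everywhere else, so matrix assembly introduces no
drift. Curves are evaluated on evenly spaced priors over [0.01, 0.99]
(default 99 points, step 0.01), covering the unit interval without
boundary degeneracy.

"Stability" has no canonical numeric definition, so the package adopts
a documented convention: a claim is stable at a threshold when the
priors whose posteriors meet the threshold cover the entire reasonable
band, default [0.05, 0.20] (skeptical to optimistic). The meeting set
is reported over the supplied *grid points* — no interpolation is
implied — while the break-even prior (1/(1+BF) at threshold 0.5) is
reported analytically alongside. The threshold comparison is inclusive:
at the break-even prior the posterior equals the target exactly and
counts as meeting it.

## Proportional synthesis

Bayes factors are binned into Jeffreys-style categories (below 1 favors
the null; 1–3 anecdotal; 3–10 moderate; 10–30 strong; 30–100 very
strong; above 100 extreme), with the boundary value 3 rendered
"anecdotal-to-moderate" and 1 rendered "no evidential shift".
Posteriors are binned into belief bands at edges 0.33 / 0.5 / 0.85:
these anchor "tentative" language near 0.3, "below even odds" at 0.5,
and "confident" language near 0.9. Both edge sets are conventions, are
configurable, and are printed in every report.

The verdict compares the claim's stated strength (a manual input — the
package does not mine text) against the belief band on a shared
three-level scale; language above the warranted band is over-claiming.
The belief band is taken at the *most optimistic* prior considered, so
an over-claimed verdict survives the claim's most charitable reading.

Rendered markdown tables show odds at 3 significant figures and display
the posterior odds as the product of the *displayed* prior odds and the
Bayes factor, so the printed table is arithmetically consistent at its
own precision (e.g. prior 0.05 shows odds 0.0526 and posterior odds
0.1578 = 0.0526 x 3, while the full-precision posterior odds are
3/19 = 0.1579). Full-precision values are always available in the JSON
rendering, which round-trips losslessly and re-validates the update
equation on the way in, rejecting hand-edited posteriors.

## Simulation and calibration

The study-batch simulator draws t statistics from their definitional
construction t = (Z + d sqrt(N_eff)) / sqrt(V/df) with Z standard
normal and V chi-squared, using a named, explicitly seeded numpy
generator so batches regenerate bit-for-bit. It emulates clean
two-group (or one-sample) designs with a common true standardized
effect: no publication bias, no heterogeneity across studies, no
optional stopping. Calibration results on these batches therefore show
that the Bayes-factor machinery behaves as the theory demands under
ideal sampling — notably the universal null bound
Pr(BF10 >= c | H0) <= 1/c — and not that any real literature is free of
the biases the simulator omits.

Problem sizes used by the shipped checks: the Monte-Carlo oracle for
the JZS quadrature uses 10^6 Cauchy draws per grid point over
t in {0, 1, 2, 3, 5} x df in {10, 28, 100}; the null-calibration check
uses 10,000 simulated studies at df = 28; the reverse-solver round-trip
uses 1,000 random (prior, BF, target) triples.

## Known limitations

- Only one- and two-sample t designs are translated; ANOVA, regression
  and correlation designs, informed non-Cauchy priors, and effect-size
  posterior estimation are out of scope.
- Evidence combination is the naive product; no joint-data or
  hierarchical meta-analytic Bayes factor is attempted.
- The claim-strength input is a manual reading of the original wording;
  the package deliberately does not automate claim extraction.
- Band edges and the reasonable prior band are documented conventions;
  conclusions near an edge should be read with the printed edges in
  mind.
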
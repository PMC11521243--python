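# Methods

This note records the models implemented, the numeric conventions chosen
where the published tables left them open, what the synthetic generators
do and do not emulate, and the known limitations.

## SeDeM radius conversion

Each parameter has a limit range and one of three transforms:

| parameter | unit | limits | radius |
|---|---|---|---|
| Da, Dc | g/mL | 0–1 | r = 10v |
| Ie | – | 0–1.2 | r = 10v/1.2 |
| IC | % | 0–50 | r = v/5 |
| Icd | N | 0–200 | r = v/20 |
| IH | – | 3–1 | r = 10(3−v)/2 |
| θ | deg | 0–50 | r = 10 − v/5 |
| t″ | s | 0–20 | r = 10 − v/2 |
| %HR | % | 0–10 | r = 10 − v |
| %H | % | 0–20 | r = 10 − v/2 |
| %Pf | % | 0–50 | r = 10 − v/5 |
| Iθ | – | 0–0.02 | r = 500v |
| effervescence | min | 0–5 | r = 10 − 2v |
| DCD, DSD | s | 0–180 | r = 10 − v/18 |

These are the standard SeDeM limits; they are internally consistent with
the shipped radius tables (e.g. ludipress' bulk/tapped densities
back-derived from r = 3.80/7.10 give an interparticle porosity radius of
10.19, exactly the shipped above-ten value). The 3-minute ODT
disintegration limit motivates the 0–180 s ranges of DCD/DSD.

Radii are **not capped** at 10 by default, matching the published 10.19;
capping is available (`convert_parameters(..., cap=True)`). Values beyond
the worst limit clip to radius 0 with a warning; values outside a limit
range warn but do not fail, since real measurements occasionally overshoot.

## Incidences, indices, rounding

Incidences are plain arithmetic means of their member radii. The published
disgregability incidences sit 0.05–0.09 below the mean of the three
printed member radii — an offset the source never explains; this package
implements the simple mean and ships the published values for reference
without asserting them.

IP counts radii ≥ 5 (a radius exactly 5 is acceptable — this is what
reproduces the published blend IP of 10/15 = 0.67). IGC/IGCB multiply the
*unrounded* mean by the reliability factor before rounding. The factors
f₁₂ = 0.952 and f₁₅ = 0.950 are fixed constants: they reproduce every
published IGC/IGCB from the published IPPs, whereas the regular-polygon
area ratios (0.9549, 0.9712) do not. Verdict bands: index ≥ 5 → "A",
3 ≤ index < 5 → "corrigible", < 3 → "inadequate".

All reported radii, incidences and indices are rounded half-up at two
decimals (the table convention; `decimal.ROUND_HALF_UP` after collapsing
binary representation noise so that an exact decimal tie like 7.085 rounds
to 7.09). Chained computations always use full precision.

## Corrective dose

CP = 100(RE − R)/(RE − RP). Under ideal linear blending of incidence radii
this is the *maximum API share* at which the deficient incidence reaches
the target R (default 5); its complement 100 − CP is the *minimum
corrective-excipient share*. For the compressibility pair RE = 7.07,
RP = 3.00 the formula gives CP = 50.86, hence a minimum ludipress share of
49.14% — the two readings of the same equation. The function returns the
formula value; edge policy: RP ≥ R → 0 (nothing to correct), RE ≤ R →
error (the excipient cannot reach the target), RE ≤ RP → error, results
above 100 clamp with a warning.

## Radar geometry

Vertices at angles π/2 − 2πk/n (first parameter at the top, clockwise,
the diagram convention), radius r_k; area by the shoelace formula, which
reduces to (n/2)·sin(2π/n)·R₀² for constant radii. The canonical parameter
order is the shipped tables' column order.

## Central composite design and compositions

Two factors, 4 factorial + 4 axial + n_center center runs; axial distance
α = √2 makes the design rotatable (prediction variance constant on circles
about the center — verified as a test property). Default centers/steps:
ludipress 52 ± 3%, croscarmellose 3 ± 2%; run order is the canonical
published order F1 = (−1,−1), F2 = (+α,0), F3 = (−1,+1), F4 = (0,0),
F5 = (0,+α), F6 = (−α,0), F7 = (0,−α), F8 = (+1,−1), F9 = (+1,+1), with
extra center replicates appended. Only one center run is generated by
default, matching the published nine-run table (a replicated center is a
single argument away).

Percent levels and milligram entries are *truncated* (not rounded) to
three decimals for display, the published convention (56.242, 47.75…).
The published milligram table itself mixes level precisions between runs
(one axial run was computed from the 4-decimal level, three others from
display-truncated levels); the shipped fixture therefore records, per run,
the level implied by the published milligrams (`*_pct_as_used`), and the
golden tests reproduce every published weight and milligram entry exactly
under 3-decimal truncation from those levels.

Composition arithmetic: API% = 100 − Σ excipient%, tablet weight =
API dose/(API%/100), mg_i = %_i × weight/100. The default fixed excipients
are aerosil 0.14%, talc 2.36%, aspartame 1%, magnesium stearate 1%; API
dose 100 mg.

## Response surfaces

OLS on coded factors (statsmodels), linear `1 + c1 + c2` or full quadratic
`+ c1c2 + c1² + c2²`. ANOVA is the classical regression partition against
the intercept-only null: F = MS_model/MS_residual, p from the F
distribution (significance threshold 0.05, configurable downstream).
Adequate precision = (max fitted − min fitted)/√(p·MS_res/n), the
design-of-experiments signal-to-noise statistic, "adequate" above 4; it is
scale-invariant and reported as +∞ (flagged) for an exact fit. Constant
responses are flagged degenerate with F = 0 rather than raising. Rank
deficiency raises an error naming the aliased columns.

The published model F-values (39.89/19.82/5.49) and adequate precisions
(15.246/11.346/5.73) could not be asserted — the response table behind
them is not available at full precision — so the ANOVA machinery is
validated by oracle equivalence instead: on 200 noisy synthetic surfaces
the F, p and adequate-precision values agree with first-principles
recomputations to 1e-9 relative.

## Release kinetics

All four models are fitted by least squares **on the release scale** so
their r² values are comparable:

- first order: Qt = Q0(1 − e^(−k1 t)) — the cumulative-release convention
  of dissolution software; the textbook log-decay regression of the
  remaining fraction is available as `first_order_decay_fit`;
- Higuchi: Qt = kH√t, closed form kH = Σ(Qt√t)/Σt;
- Hixson–Crowell: Qt = Q0 − (Q0^⅓ − kHC t)³, kHC bounded so the cube root
  stays non-negative on the grid;
- Weibull: Qt = Q0(1 − exp(−(t − Ti)^β/α)), lag Ti pinned at 0 by default
  (an ODT releases immediately; the published fits report no lag), fitted
  by bounded least squares from five fixed starting points.

r² = 1 − SS_res/SS_tot on observed release, unadjusted, for cross-model
comparability. Points at/after complete release are trimmed to the first
≥ 100% observation, since the log and cube-root forms degenerate there.
Model selection is argmax r² with exact ties broken toward fewer
parameters. Rate constants carry the time unit of the input grid (the
default grid is 2–15 minutes; the published table labels its constants per
hour, an inconsistency the package does not inherit).

The published r² values themselves are not asserted (the underlying
dissolution percentages were published only graphically); they serve as
the model-selection fixture — on them the selector returns "higuchi" for
all nine formulations, the study's conclusion — and as generator truth
constants for round-trip and Monte-Carlo recovery tests (noise-free
recovery to 1e-6; median Higuchi-rate bias < 0.5% at σ = 1% over 500
seeds).

## Stability and shelf life

OLS of assay on months; shelf life is the earliest t ≥ 0 where
ŷ(t) − t₍conf,df₎·s·√(1/n + (t − x̄)²/Sxx) ≤ spec limit, found by a
4097-point bracketing scan over [0, horizon] followed by bisection to
0.001 month (the bound is smooth but not monotone left of x̄, so the scan
guards the bracket). Defaults: spec limit 90% of label claim (a common
assay specification; configurable), one-sided 95% bound on the mean,
horizon 600 months, response = assay (dissolution/disintegration series
are carried alongside and selectable). A zero-residual fit collapses the
bound onto the mean line, giving the closed form
(intercept − limit)/|slope| exactly. No accelerated→long-term
extrapolation factor is applied, and formulations are fitted separately
(no poolability testing).

With only three time points the t quantile has one degree of freedom and
the bound is extremely conservative; the published month-range shelf life
(for which neither the response, the limit, nor the confidence convention
was stated) is treated as a plausibility reference only. On the shipped
nine accelerated series the default settings give finite, positive
estimates for every formulation (≈ 9.5–155 months).

## Quality checks

Weight variation is the simple tier test — every tablet within ±7.5% of
the batch mean (the tier for 130–324 mg tablets, which all nine batches
occupy); the full two-stage compendial procedure is out of scope.
Friability < 1%, disintegration < 180 s (the ODT limit), assay within a
configurable 95–105% band. Missing measurements are reported "not
evaluated", never failed. The shipped quality table passes every check for
all nine batches; its F4 dissolution entry was published as "990.66",
carried as 99.66 (flagged in the fixture) since a percent release cannot
exceed ~105.

Individual tablet weights were not published — only mean ± sd — so the
weight-variation check of the shipped batches uses the two-point envelope
mean ± sd; the sd values (≈ 1%) are an order of magnitude inside the 7.5%
tier, so the verdict is insensitive to this stand-in.

## Synthetic data

Generators are pure functions of (seed, parameters) on NumPy's PCG64
stream, fixed so fixtures are portable. They emulate: powder values
uniform within each SeDeM limit range (optionally biased toward a target
profile index via N(target, 1) radii, or pinned per parameter); model-true
dissolution curves on the 7-point minute grid with additive Gaussian noise
clipped to [0, 105]%; linear degradation with Gaussian noise at 0/3/6
months (configurable grid); response surfaces with stated coefficients and
noise on the CCD runs.

They do **not** emulate: correlations among powder parameters (real
densities, Carr index and Hausner ratio are functionally related),
heteroscedastic or serially correlated dissolution noise, batch effects,
or non-linear degradation. Passing recovery tests therefore demonstrates
the estimators' correctness under the stated noise model, not robustness
to real-world measurement pathologies.

Simulation sizes used in the test suite — 200 ANOVA replicates, 500
dissolution seeds, 500 stability series — are the package's chosen
defaults for stable Monte-Carlo medians; each individual fit is closed
form or one-dimensional, so the full suite runs in seconds.

## Known limitations

- The SeDeM limit table is the standard one; laboratories using modified
  limits must supply their own `ParameterRule`s (supported).
- Two-factor designs only; no blocking, no desirability optimization.
- No Korsmeyer–Peppas/zero-order models, f1/f2 similarity factors, or
  IVIVC.
- No Arrhenius temperature extrapolation in the stability stage.
- The pipeline's design stage recomputes compositions from the
  display-truncated levels (self-consistent); reproducing the published
  milligram table exactly requires the per-run `as_used` levels shipped in
  the fixture, owing to the source's mixed precision.
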
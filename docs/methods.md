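# Methods

This note records the models behind `dopacycle`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Shine–Dalgarno space and RBS strength

RBS engineering is restricted to the six-nucleotide SD core; flanking
sequence and mRNA secondary structure are deliberately out of scope. The
design space is therefore the 4⁶ = 4,096 hexamers over {A, C, G, T}
(enumerated in fixed lexicographic order A < C < G < T so design sheets are
byte-for-byte reproducible) and 4⁶ × 4⁶ = 16,777,216 ordered pairs for the
bi-cistronic operon. GC content is kept as an exact multiple of 1/6
(`fractions.Fraction`) and only rendered as a percentage (one decimal,
half-away-from-zero) at reporting boundaries.

Strength is summarized by a log-linear model, `log TIR = a + b·GC`, with the
slope sign free per gene context: empirically GC strengthens the RBS of
*hpaBC* and weakens that of *ddc*. Only the monotone direction is
established; the log-linear form is a configurable stand-in, and TIR units
are arbitrary because only TIR ratios are consumed downstream. Two wordings
of the pairing rule circulate for ratio matching ("multiplied" vs a ratio);
the worked example "2:1 ⇒ numerical ratio 0.5" fixes the implemented
contract: the matched quantity is `TIR_ddc / TIR_hpaBC`, compared to the
target in log space so that k-fold mismatches in either direction are
penalized equally. Ties break lexicographically on (hpaBC sequence, ddc
sequence).

## Crude-lysate cascade

States TYR, DOPA, DA (dopamine) and MEL (melanin sink) in mM evolve under
two Michaelis–Menten steps with fixed-total-volume mixing: at lysate volume
ratio r (HpaBC:Ddc), the HpaBC lysate fraction is r/(r+1) and the Ddc
fraction 1/(r+1), so boosting one enzyme dilutes the other. An optional
first-order loss k_ox·[DOPA] models spontaneous l-DOPA oxidation. Mass is
conserved exactly by construction; the integrator (LSODA via
`scipy.integrate.solve_ivp`, relative tolerance 1e-8, absolute floor 1e-12
mM) must preserve it to within 10·rtol, and states are clipped to zero only
within solver round-off — larger negativity raises an error carrying the
last accepted state. Enzyme activities are treated as constant over the
20 h horizon (no lysate decay): a stated simplification.

Defaults: substrate 1 mM l-tyrosine, 20 h duration (the lysate reaction
protocol); Km_Ddc = 0.092 mM (the characterized value for l-DOPA);
Km_HpaBC = 0.1 mM for l-tyrosine — HpaBC is not fully characterized on this
substrate, so a value interior to the 0.0094–0.514 mM range reported for
related substrates is used and exposed as configuration; k_ox defaults to 0
because no in vitro melanin quantification is available.

The maximal-rate pair (Vmax_HpaBC = 0.05 mM/h, Vmax_Ddc = 30 mM/h at lysate
fraction 1) is calibrated to the *qualitative* titration trend only —
absolute in vitro titres are not available numerically. The calibration is
forced by arithmetic: for dopamine to keep rising up to 100:1, the diluted
Ddc capacity Vmax_d·t/(r+1) at r = 100 must still exceed the ~1 mM of
substrate HpaBC can convert, while HpaBC at 1:1 must remain far from
completion; both together require Vmax_d/Vmax_h of several hundred, and a
generous Ddc reserve also keeps the quasi-steady l-DOPA residual (which
grows with r) from eating the shrinking tail increments. A ratio of 20,
which a superficial "Ddc is more efficient" reading might suggest, produces
a non-monotone curve under fixed-volume dilution. With the default preset
the 1:1 → 100:1 titration roughly doubles final dopamine with a concave,
converging tail; the in vivo-style optimum criterion (`optimal_ratio`)
breaks ties toward the smaller ratio.

## Design strategies

Strategy A selects, per enzyme-ratio target, the `n_per_target` pairs
minimizing |ln(TIR ratio) − ln(target)| over the full hpaBC × ddc cross
product (exhaustively checked against a brute-force oracle in the tests).
Strategy B draws a seeded sample stratified over the 7 × 7 grid of GC levels
of both contexts — an interpretation of "handpicked to screen the parameter
space" — and always includes the strongest-TIR candidates of both contexts
and the AGGAGA/AGGAGA reference pair when present. The canonical layout is
15 Strategy A + 41 Strategy B = 56 designs labeled A.01… / B.01…; how the 15
distribute over the seven titration points is not fixed (two per point is
the stated minimum), so the sheet builder accepts any per-target counts and
`campaign_layout_sheet` gives the first point a third pick. A sequence pair
appearing in both strategies is kept once and tagged "A+B", so a sheet can
occasionally have fewer than 56 rows.

## Test-and-learn conventions

Success rates are percentages of designed constructs passing a build stage,
reported to one decimal (half-away-from-zero); fold-changes to one decimal;
percent increases to the nearest integer — raw values are available via
`rounded=False`. Unit conversions use molar masses summed from an embedded
IUPAC-2021 conventional atomic-mass table (dopamine C₈H₁₁NO₂ = 153.18
g/mol, l-DOPA C₉H₁₁NO₄, l-tyrosine C₉H₁₁NO₃), so results are bit-stable
across environments. Specific yield is titre divided by biomass; the default
biomass scenario value, 69.03/34.34 ≈ 2.01 g/L, is back-computed from the
two headline numbers because biomass itself is not printed anywhere.

The GC analysis fixes one context inside a GC band (default 0.8–1.0),
requires at least three in-band strains, and reports the sign, magnitude and
sample size of Spearman's rank correlation between the free context's GC
and dopamine titre. Rank correlation is used because only a direction, not a
functional form, is claimed. l-DOPA accumulation is flagged when the
per-design mean l-DOPA:dopamine ratio exceeds a threshold (default 1.0, a
free parameter since no published cutoff exists), with a 1e-9 mg/L guard on
the denominator.

The learn-stage estimator `estimate_optimal_expression_ratio` fits
`ln titre ~ b0 + b1·ln TIR_h + b2·ln ρ + b3·(ln ρ)²` with
ρ = TIR_h/TIR_d by least squares and returns the vertex exp(−b2/2b3),
requiring concavity. The linear `ln TIR_h` term absorbs absolute-expression
effects so the quadratic isolates the ratio response. In the Monte-Carlo
recovery experiment the per-context strength models are first refit to the
library and designs are scored with the smoothed model prediction instead of
their single noisy TIR measurement; this removes most errors-in-variables
attenuation in the vertex estimate.

## Synthetic response surface

The generator plants, in noise-free form:

* expression maps `expr = exp(a + b·GC)` with b = +1.5 (hpaBC) and −1.5
  (ddc). Magnitudes are free defaults — a ~4.5-fold strength range per
  context across the GC axis, comparable to characterized SD libraries;
* a titre surface `titre ∝ (expr_h / expr_h(GC=1))^γ ·
  exp(−ln²(ρ/ρ*) / 2σ²)` with optimal expression ratio ρ* = 2.6, width
  σ = 0.9 and capacity exponent γ = 2.5, normalized so its maximum over the
  7 × 7 GC grid equals 69.03 mg/L (a scenario constant, not a fitted value).
  The log-Gaussian factor makes titre unimodal along the ratio axis with a
  closed-form peak; the capacity factor is required for internal
  consistency: with log-linear maps, a surface depending on the ratio alone
  cannot simultaneously make titre fall in gc_ddc at GC-rich hpaBC *and*
  fall with decreasing gc_hpaBC at GC-rich ddc — the two sign conditions are
  jointly infeasible linear inequalities. With (b, σ, γ) as above and the
  ddc intercept placing the all-AT corner 1.1 log units below ρ*, both
  trends hold over the stratified bands and the surface peaks at
  (GC_hpaBC, GC_ddc) = (1, 0), the high/low corner;
* an l-DOPA leak of 40 mg/L per log unit of ratio overshoot above ρ*
  (insufficient Ddc), zero below it;
* multiplicative lognormal measurement noise with CV 1.2/69.03 ≈ 1.7% (the
  relative error of the headline titre), mean-preserving; biomass around
  2.01 g/L with CV 2%; TIR library noise 0.15 log units (~15%), a typical
  reporter-assay spread.

What the generator does *not* emulate: translational coupling between the
two cistrons, sequence-specific effects beyond GC content (two hexamers with
equal GC are interchangeable), growth differences between designs,
point-mutation sequence failures (the build log draws Bernoulli stage
outcomes on a monotone ladder only), and day/batch effects. Passing
recovery tests therefore shows that the pipeline's inference is sound under
its own stated noise model — not that real cohorts obey log-linear GC maps.

## Problem sizes and determinism

Every generator takes a mandatory seed and is a pure function of its
arguments; `numpy.random.default_rng` streams are never shared implicitly.
The Monte-Carlo experiments use 100 seeds (ratio recovery, 56-design
cohorts, 48 library entries per context, triplicates) and 200 cohorts (GC
trend signs); the build-funnel expectation uses 2,000 seeds. These sizes
give stable rates while keeping the whole suite and the acceptance script in
the seconds-to-minutes range on a single CPU. Solver-versus-oracle checks
run a fixed-step Euler reference at 1e-4 h on horizons of ≤ 2 h, where its
truncation error stays well below the 1e-4 relative comparison; comparisons
avoid states driven to within ~1e-5 mM of depletion, where any fixed-step
oracle's own error dominates a relative metric.

## Known limitations

* The in vitro preset reproduces a trend, not absolute titres; fitting
  kinetic parameters to titration data is out of scope.
* The cascade ignores cofactor balances (FADH₂, PLP), oxygen transfer and
  lysate aging.
* TIR is treated as a perfect proxy for in vivo expression up to noise; the
  in vitro → in vivo transfer gap that motivates GC-based re-analysis in
  real campaigns is represented only through the GC-dependent truth maps.
* No free-energy or secondary-structure RBS modeling, and no sequence-level
  simulation of build failures.
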
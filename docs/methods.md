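# Methods

## The capture network and its flux model

The analysis targets a non-growing *E. coli* strain expressing
phosphoribulokinase (PRK) and a Rubisco, fermenting xylose and glycerol to
d-lactate under anaerobic, ¹³C-bicarbonate-buffered conditions. The network
is deliberately small and fixed:

- Xylose uptake `Xyl_total` splits into a pentose-phosphate flux `X₁` and a
  bypass flux `X₂` (xylose → Ru5P → RuBP → carboxylation). Each
  carboxylation consumes one CO₂, so `X₂` *is* the CO₂-uptake flux.
- Pentose-phosphate rearrangement converts `X₁` pentoses into `(5/6)·X₁`
  hexoses; with two G3P per hexose and glycerol entering at G3P, the
  glycolytic G3P flux is `X₃ = (5/3)·X₁ + Gly_total`.
- Each carboxylation yields two 3PGA, exactly one of which carries the
  labeled carboxyl carbon. Mixing `X₃` unlabeled 3PGA (via GAPDH) with
  `2·X₂` bypass 3PGA gives the labeled fraction of the pool — and of the
  lactate drawn from it —

      R = X₂ / (X₃ + 2·X₂).

Substituting `X₁ = Xyl_total − X₂` makes R strictly increasing in `X₂` with
supremum 1/2, and the inversion is closed-form:

    X₂ = R · ((5/3)·Xyl_total + Gly_total) / (1 − R/3).

The implementation uses this closed form; the test suite checks it against
scalar root-finding (Brent bisection) on the forward map to 1e-10 over
random instances, and property tests (hypothesis, derandomised) cover the
round trip, monotonicity and the R < 1/2 bound.

Assumptions worth making explicit: single labeling only (only the Rubisco
carboxyl carbon is ¹³C; multiply-labeled lactate is assumed absent),
steady-state pools over the analysis window, and a labeled pool that
requires xylose-derived RuBP — a nonzero R with zero xylose uptake is
rejected as inconsistent rather than attributed to glycerol.

## Rates from time courses

The capture phase is a resting-cell batch: biomass holds near its initial
OD₆₀₀ (default 2.0) and concentrations change linearly. A specific rate over
a window [t₀, t₁] is the endpoint difference quotient |ΔC|/Δt divided by
biomass (window-mean OD₆₀₀ × 0.3 gDCW L⁻¹ per OD unit), in
mmol gDCW⁻¹ h⁻¹. A least-squares-slope estimator and a per-sample biomass
mode are provided as options; the endpoint quotient with constant biomass is
the default and is what all reference numbers use. The default window is
the last 12 h of the series.

The labeled-lactate fraction is computed from window increments: labeled
lactate accumulated minus the control strain's labeled-lactate accumulation
over the same window (the background), divided by total lactate
accumulated. Without a control course the fraction is uncorrected; a
negative corrected numerator is clipped to zero.

## Ledgers

**Carbon.** Rates × carbon atoms (xylose 5, glycerol 3, lactate 3, acetate
2, ethanol 2, CO₂ 1). The CO₂ released during pyruvate dissimilation is not
measured; it is estimated as one CO₂ per acetate plus one per ethanol, the
only decarboxylations in the network. Recovery is total produced carbon
(products + released CO₂) over total consumed carbon (substrates + CO₂
uptake). Under the ideal stoichiometry (xylose + 2 glycerol + CO₂ →
4 lactate) recovery is exactly 1, a property the synthetic generator and
test suite exercise.

**NADH.** Consumption: one per lactate, one per ethanol. The
one-per-ethanol convention counts the reduction as a single accounting
event even though ethanol formation from acetyl-CoA uses two reduction
steps biochemically; it is the one-NADH-per-reaction convention of the
reference accounting, and it is the only convention that closes all three
reference strains' ledgers. Production: one per glycerol oxidised
(glycerol → glycerone) plus one per G3P through GAPDH. Only `X₃` passes
GAPDH — the two 3PGA per carboxylation enter *below* GAPDH — so production
is `Gly_rate + X₃`. The reported quantity is the consumption/production
ratio (printed in the reference table as "net flux of NADH"); both terms
are exposed so the definition can be audited. A ratio above 1 marks a
redox-infeasible flux set; the labeling model is stated under the premise
production ≥ consumption, so infeasible cases are flagged, not errored.

**Uncertainty.** The measured rates carry standard deviations; ledger
uncertainties are propagated by Monte Carlo: each rate is drawn
independently from a normal with its mean/SD, truncated at zero (a bias
source for near-zero rates), a drawn CO₂ uptake is clamped to the drawn
xylose supply (rare tail draws), the ledgers are recomputed, and sample
means/SDs are reported. Default 10⁵ draws, seeded; 10⁴ in the report
pipeline. A replicate-wise alternative (recomputing ledgers per biological
replicate) would be equally defensible but requires the raw replicates,
which the reference tables do not carry.

**Rounding.** Comparisons against printed tables round half away from zero
at the printed decimal count, on the shortest decimal representation.

## Kinetics and expression

Michaelis–Menten fitting uses lmfit's nonlinear least squares with
kcat₀ = max observed rate, K_M₀ = concentration nearest half-max, both
parameters bounded positive. Standard errors come from the fit covariance;
the catalytic efficiency `k_cat/K_M × 1000` (s⁻¹ mM⁻¹) gets a first-order
(delta-method) SD including the parameter covariance. Fits are
scale-equivariant (rates × c → kcat × c, K_M unchanged). A design with
fewer than three distinct concentrations warns; one concentration is
rejected as unidentifiable. Dissolved-CO₂ preparation chemistry is out of
scope — assay concentrations are taken as given.

CABP titration counts active sites, not holoenzymes. The %CSP calculation
therefore defaults to a per-site mass of one large subunit
(322 kDa hexamer / 6 ≈ 53.7 kDa); the holoenzyme mass is accepted via the
`site_molar_mass` argument for the alternative convention. The published
convention is ambiguous on this point, so the default is a documented
package choice, not a claim about the original calculation. Specific
activity is nmol CO₂ fixed min⁻¹ mg⁻¹ total soluble protein; turnover is
nmol fixed / nmol sites / second.

## Synthetic data

The generator emulates the resting-cell batch, not a general fermentation:
constant biomass (OD₆₀₀ 2.0), constant specific rates, hence linear
concentration courses, with substrate-exhaustion clipping so nothing goes
negative. Defaults are the RPE-like condition (xylose 0.50, glycerol 0.46,
bypass 0.18, lactate 1.01, acetate 0.18, ethanol 0.06 mmol gDCW⁻¹ h⁻¹),
sampled every 12 h for 72 h. Initial loadings are sized ~1.5× the 72 h
consumption of that rate set (≈5 g/L xylose, ≈2.5 g/L glycerol), the usual
design for a conversion batch that should end near, but not at, exhaustion.
Labeled lactate accumulates at the model-implied fraction of the lactate
rate plus a constant background of 1 mM per 72 h, matching the labeled
titer observed in bypass-inactive controls; the background's biochemical
origin is not modelled. Measurement noise is Gaussian per concentration
sample with a per-species CV (truncated at zero); assay noise is
multiplicative lognormal with unit mean. All randomness flows through one
integer seed.

What passing tests do and do not show: the generator shares the analysis
model's structure (constant rates, single labeling, exact stoichiometry),
so recovery tests validate the *inference machinery* — estimator
correctness, inversion, background correction, noise robustness — not the
biological adequacy of the model. Real courses with early-phase rate
drift, growth, label recycling or multiply-labeled species are outside
what these tests certify.

Noise-robustness tests analyse the full simulated batch (0–72 h) rather
than the last-12 h default window: simulated rates are constant
throughout, so the full span is the statistically efficient choice, while
the short default window mirrors the reference analysis where early rates
may differ. At 5 % CV the median relative error of the recovered bypass
flux over 100 seeded runs is ~6 %; the last-12 h window alone is
intrinsically ~5-fold noisier (endpoint increments of cumulative series
under proportional noise).

## Numerical choices and limitations

- Tolerances: partition identities are enforced to 1e-9 relative;
  inversion-vs-oracle agreement is tested to 1e-10; unit conversions are
  exact pass-through for canonical units.
- Degenerate inputs error early with specific messages (zero biomass,
  non-positive lactate accumulation, label fraction outside [0, 1),
  inferred bypass above xylose supply, zero active sites).
- Problem sizes: the test suite runs 100–200-seed simulation sweeps and
  the acceptance script a 100-seed sweep plus 13-point × 3-replicate assay
  fits; everything completes in seconds.
- No ATP balance is computed; no genome-scale model, isotopomer/EMU
  machinery, growth kinetics or oxygenation kinetics are included — the
  label bookkeeping is exactly the single-fraction model above, which is
  the point of the artifact.
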
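# Methods

## The chemistry being modelled

Magnesium chelation, Mg²⁺ + D_IX ⇌ MgD_IX, is thermodynamically uphill
(association constant K_eq ≈ 10⁻⁶ M⁻¹ with molar concentrations;
standard state c° = 1 M, so ΔG°′ = −RT ln K_eq ≈ +35 kJ·mol⁻¹ at
307.15 K). The reverse reaction — dechelation — is first-order in the
metalloporphyrin with rate constant k_dechel ≈ 3.17×10⁻⁵ s⁻¹. By
microscopic reversibility, treating insertion as a bimolecular process,
the uncatalyzed forward constant is k_uncat = K_eq·k_dechel ≈
3×10⁻¹¹ M⁻¹·s⁻¹: at 1 mM free Mg²⁺ the pseudo-first-order half-life is
ln 2/(k_uncat·[Mg²⁺]) ≈ 0.7 million Julian years. The chelatase both
accelerates this reaction and, by hydrolyzing ATP, holds its product far
above the equilibrium ratio; the package computes both measures and
simulates the assays in which they are observed.

## Dechelation fitting

Initial rates are extracted from concentration time courses as the
magnitude of an OLS slope over a window starting at t = 0 (default
300 s, ≥3 points required; for k ≈ 3×10⁻⁵ s⁻¹ the chord-vs-tangent
curvature bias over 300 s is k·t/2 ≈ 0.5%). Rates are regressed on
starting concentration *through the origin* — zero rate at zero
concentration is chemically forced — with

    k = Σ cᵢrᵢ / Σ cᵢ²,   SE = sqrt( Σ(rᵢ − k·cᵢ)² / ((n−1) Σ cᵢ²) ),

and SE = 0 reported for a single point. Rates are stored as positive
magnitudes. An optional photolysis first-order term is available in the
synthetic generator but defaults to 0 (illumination controls showed
negligible photolysis over an 1800-flash time course).

## The progress-curve ODE model

State (D, MgD, ATP, PEP) in molar units, time in seconds:

    dD/dt   = −v + k_dechel·MgD          dMgD/dt = v − k_dechel·MgD
    v       = k_cat·E₀ · D/(K_m+D) · Mg^h/(K₀.₅^h+Mg^h)
                        · ATP/(K₀.₅,ATP+ATP) · 1/(1+MgD/K_i)

with E₀ = min([ChlI],[ChlD],[ChlH]) (the active complex cannot exceed
the scarcest subunit) and free Mg²⁺ clamped (10 mM against µM porphyrin
turnover). ATP is consumed at n_ATP·v plus an uncoupled basal ATPase
k_basal·[ChlI]·ATP/(K₀.₅,ATP+ATP). The separable rate-law form is a
modelling choice, not a measured mechanism: it is the simplest law in
which K_m^DIX and K₀.₅^Mg enter the proficiency expression as
independent factors. All constants are configuration.

The PEP/pyruvate-kinase regeneration system is idealized as an ATP
clamp: while PEP > 0, d[ATP]/dt = 0 and PEP is debited 1:1 at the ATP
flux (pyruvate-kinase kinetics are not modelled; 2 U·mL⁻¹ is treated as
non-limiting). Integration uses LSODA with rtol 1e-8 / atol 1e-12 on a
fixed output grid, split at the PEP-exhaustion event, after which the
clamp is released. D + MgD is conserved exactly by construction and
verified to ≤10⁻⁶ relative in tests.

The steady state solves v(D) = k_dechel·(D_total − D) with ATP clamped
at its initial value. The left side is increasing and the right side
decreasing in D, so the root is unique; it is found by Brent's method to
relative tolerance 1e-12, with boundary cases (no enzyme, no nucleotide,
k_dechel = 0) returned analytically rather than failing. Steady-state
maintenance time is the longest contiguous interval during which MgD
stays within a tolerance fraction (default 10%) of the plateau — the
supplied algebraic steady state, or the curve maximum when none is
given; pure-decay curves are flagged `no_plateau`, and curves still in
band (or still rising) at the end of the record are flagged `censored`.

### Default parameters

| parameter | default | units | provenance |
|---|---|---|---|
| k_cat | 1/75 | s⁻¹ | measured turnover (1/k_cat = 75 s) |
| k_dechel | 3.17×10⁻⁵ | s⁻¹ | measured (±0.09×10⁻⁵) |
| K_m_DIX | 2.0×10⁻⁶ | M | split of the pinned product, see below |
| K_05_Mg | 7.0×10⁻³ | M | split of the pinned product, see below |
| hill_Mg | 2 | — | Mg²⁺ cooperativity is reported; the value is not |
| K_05_ATP | 1.0×10⁻⁴ | M | ATP response saturates near 150 µM |
| n_ATP | 15 | — | measured ATP:metalloporphyrin stoichiometry |
| k_basal_ATPase | 0.7 | s⁻¹ per ChlI | calibration, see below |
| K_i_product | ∞ (off) | M | product inhibition is an open possibility |
| K_eq | 10⁻⁶ | M⁻¹ | measured equilibrium constant |
| T | 307.15 | K | 34 °C assay temperature |

Only the *product* K_m_DIX·K_05_Mg = 1.4×10⁻⁸ M² is pinned — it is what
the printed catalytic proficiency of 3×10¹⁶ M⁻¹ constrains; the 2 µM /
7 mM split is a labeled assumption. k_basal = 0.7 s⁻¹ is a calibration
chosen so that a 0.5 mM ATP pool depletes on the few-hour timescale of
an unregenerated assay and a 2 mM PEP pool sustains the steady state for
≈8 h, matching the observed behavior; it is clearly a fitted, not
measured, quantity. The Gun4-activated parameter set (k_cat =
1.744×10⁻² s⁻¹, K_m_DIX = 2.616×10⁻⁷ M) is back-computed from the
printed Gun4 rate enhancement (550×10⁶ M) and the ten-fold proficiency
increase; Gun4 is represented only as this alternative parameter set,
not as a mechanism.

With these defaults the model's steady-state product:substrate ratios
*overshoot* the measured ones (e.g. [MgD]/[D] ≈ 13 at 2.5 µM porphyrin
vs. ≈4 observed) — the measured ratios are best treated as lower limits
because of possible product inhibition or slow inactivation, which the
default model leaves off. Only the monotone trends (saturating in ATP,
decreasing with total porphyrin) are asserted, not the ratio values.

### Known free-energy discrepancies (documented, not patched)

RT ln(10⁸) = 47.0 kJ·mol⁻¹ at 307.15 K, while 53 kJ·mol⁻¹ is the number
usually quoted alongside the 10⁸ displacement factor; 53 corresponds to
a factor ≈10⁹ (which the default model's low-porphyrin steady state,
1.3×10⁹, in fact produces). Likewise −RT ln(10⁻⁶) = 35.3 kJ·mol⁻¹ sits
just above the 25–33 kJ·mol⁻¹ literature range for ΔG°′, reflecting the
order-of-magnitude nature of K_eq. The implementation reports whatever
follows from its inputs via the exact closed forms.

## Stochastic coupling

ATPase cycles are independent Bernoulli trials with success probability
p = 1/n_ATP (1/15 ≈ 6.7% for Synechocystis; 1/40 for R. capsulatus);
the AAA⁺ ring resets after each cycle, supporting memorylessness.
ATP per product is then geometric: mean 1/p, variance (1−p)/p².
The simulator draws geometric waiting times with numpy's Generator
(bit-reproducible per seed) and is checked against the closed-form pmf
by partial sums and chi-square goodness of fit. The stochastic layer is
deliberately *not* wired into the ODE model, which uses deterministic
n_ATP accounting; the two views agree in the mean. Whether the measured
stoichiometry includes chelation-independent basal hydrolysis is not
settled; the ODE's basal ATPase and the stochastic p = 1/15 are kept as
separate, labeled assumptions. Correlated or multi-site ring variants
are out of scope.

## Synthetic data

The generator emulates the two assay families at the conditions of the
standard experiments (0.1 µM ChlI/ChlD, 0.4 µM ChlH, 8 µM D_IX, 10 mM
Mg²⁺, 34 °C; panels at 0.5/1/5 mM MgATP²⁻ with and without a 2 mM PEP
regeneration pool; a low-porphyrin variant at 2.5 µM D_IX; a
dechelation experiment at 1–6 µM MgD_IX sampled every 10 s for 5 min).
The 1–6 µM concentration range and single replicate per concentration
are assumptions recorded in the preset description — the actual design
is not printed. Default noise is multiplicative with 3% CV
(plate-reader-like); the magnitude is an assumption, as no noise
statistics are published. Every generator emits its noise-free truth
alongside the noisy data for oracle use, and the truth never appears in
the noisy files. All generators are pure functions of (arguments, seed).

One structural choice deserves emphasis: the dechelation *initial-rate
table* is generated by applying the noise model to the true rates
k·c directly, not by refitting the noisy 5-min traces. Over 300 s the
decay moves the signal by only ~1%, so at 3% point noise a trace-refit
rate is noise-dominated, and the positive-magnitude convention then
biases the folded estimates upward by tens of percent. Real
measurements resolving k to ±3% must effectively operate at a much
higher signal-to-noise than the 3%-per-point/5-min combination; the
rate channel models the *outcome* of such a measurement. The noisy
traces are still generated for curve-level operations and round-trip
tests. Consequently, recovery tests on the rate table validate the
regression and its calibration, not short-window rate extraction at
high noise — that limitation is intrinsic and documented here. In the
calibration (coverage) test, the ±2 SE band uses the Monte-Carlo SD of
the fitted constant across replicates; the per-fit residual-based SE is
downward-biased under multiplicative (heteroscedastic) noise in an
unweighted through-origin fit and is checked only at the looser 3 SE
level for a single experiment.

Fluorescence is attributed to MgD_IX only (signal = gain·[MgD] +
baseline; free-base contribution zero by default) and inverted by the
same affine map with clipping at zero. Instrument drift, photobleaching
and inner-filter effects are not simulated — passing tests say nothing
about those real-data features, nor about pH/ionic-strength dependence
(assays at I = 0.1, pH 7.7–7.9 are recorded as metadata only).

## Problem sizes and numerics

Simulations run 10–12 h of assay time on a 30 s output grid (LSODA,
rtol 1e-8/atol 1e-12); the coverage study uses 500 replicates of the
6-concentration experiment; stochastic-coupling runs use 10⁵ products
(SE of the mean ≈ 0.046 at p = 1/15). These sizes make every check
sharp at desk scale. Rounding for display ("circa" style, 1 significant
figure by default) is render-only and never feeds back into stored
values. Ties and degenerate inputs: constant curves count their full
duration as maintained; curves that never rise report zero maintenance
with a flag; steady-state corner cases return boundary solutions rather
than raising.
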
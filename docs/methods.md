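# Methods

This note documents the models implemented in `ptckin`, the choices made
where the procedure was genuinely open, the synthetic-data conditions, and
what the closed-loop validation does and does not establish.

## Termination rate law with ligand depletion

The observed peptide-release rate of a pretermination complex (P₅) at free
release-factor-complex concentration x is

    k_obs(x) = k_cat · xⁿ / (xⁿ + Kⁿ),   n ∈ {1, 2}.

n is restricted to {1, 2} rather than fitted continuously: the data this
analysis targets are either clean rectangular hyperbolas (one effective
RFC site) or clearly S-shaped (positive homotropic cooperativity
consistent with a second site), and a free Hill exponent would be poorly
identified on 8-point titrations. K is reported as K_M^RFC when n = 1 and
K_A^RFC when n = 2.

Titrations are run at complex concentrations (P₅ = 50 nM) comparable to or
above K, so bound RFC is a large fraction of total. Free RFC is recovered
from the equilibrium mass balance

    Kⁿ·RP₅ = (RFC_total − n·RP₅)ⁿ · (P₅_total − RP₅),

taking stoichiometric consumption of n RFC per productive complex. For
n = 1 this is a quadratic in RP₅, solved on the numerically stable branch
2RP/(b + √(b² − 4RP)); for n = 2 a cubic, solved by Brent's method on the
physical interval [0, min(P₅, RFC_total/2)], where the residual is
strictly increasing and brackets with opposite signs for all valid inputs
(root tolerance 1e−12 nM). The solve is applied *inside* the nonlinear
fit: every candidate K implies its own free-RFC values at every titration
point (full self-consistency, not a one-shot correction).

Fitting uses `scipy.optimize.least_squares` on log-parameterized
(k_cat, K) with three K starts (the half-max crossing and ±10×), keeping
the best optimum. Parameter SEs come from the Gauss–Newton covariance,
delta-method transformed to the natural scale. Unweighted least squares is
the function-level default; the pipeline and validation use
inverse-variance weighting from the per-point SEs, which is the
appropriate estimator when k_obs noise is relative (and is required in
practice for stable cooperative fits). Fitted K ≤ 1 nM is flagged
`at_detection_limit` — below the lowest usable complex concentration, K is
a bound, not an estimate.

**Identifiability caveat.** When K ≪ P₅ (e.g. K = 10 nM at P₅ = 50 nM),
binding is nearly stoichiometric and the titration shape is dominated by
consumption of the complex rather than by K. A Cramér–Rao computation at
the standard design (8 points, 0–120 nM, 10% relative noise) puts the
*lower bound* on the relative SE of K near 1.0 for that regime, for every
8-point design we tried: single-series K estimates there are unbiased in
median but scatter roughly two-fold. Estimates of K for the cooperative
class (K ≈ 28 nM, closer to equivalence) are far better determined
(median error ~10%). Replicated titrations or lower complex concentrations
are the physical remedies, not a better optimizer.

## Model-shape selection

The hyperbolic and cooperative models have the same parameter count, so
the usual nested F-test does not apply directly. We treat the discrete
switch in n as one effective parameter: F = (RSS₁ − RSS₂)/(RSS₂/(N − 2))
with (1, N − 2) degrees of freedom, selecting n = 2 only when it both
lowers the RSS and passes at α = 0.05. AICc comparison is available by
configuration. The same F-test (2 extra parameters) arbitrates single
versus biphasic anisotropy decays; the reported k_obs is always the
fast-phase rate, and phases are relabeled if the optimizer returns them
inverted.

## Readthrough and the competition model

Readthrough efficiency is signal over the cognate-control signal, mapping
both assay formats (co-sedimentation counts; ΔF at 2 min) onto one 0–1
scale with the cognate control ≡ 1. The generative competition model
treats the A site as a race between productive suppressor-TC binding
(pseudo-first-order rate a·[TC]) and termination at the prevailing free
RFC:

    p_rt = a·[TC] / (a·[TC] + k_term),
    k_term = k_obs(RFC_free; k_cat, K·(1 + [ataluren]/K_i), n).

Ataluren enters as a competitive inhibitor (apparent-K scaling with
single-site K_i); G418 multiplies a without touching k_term; an
anticodon-edited suppressor tRNA is a cognate-level TC. The association
rate is calibrated once so the reference context (k_cat = 0.2 min⁻¹,
K_A = 28 nM, n = 2) shows 20% basal readthrough at 0.2 μM TC and 50 nM
RFC. K_i is a free generator parameter (default 0.3 mM; no measured value
exists): in the panel simulation each context receives an effective K_i
that realizes its generative ΔRE through the competition model. That
per-context sensitivity absorbs what the single-site picture omits — in
particular the cooperative class responds less to ataluren than its K
alone would suggest, consistent with a second RFC site that the inhibitor
does not touch.

## Combination verdicts

For a two-agent experiment with baseline b, single-agent REs r_A, r_B and
combination r_AB (each mean ± SD of ≥3 replicates), the additive
prediction is b + (r_A − b) + (r_B − b), capped at 1. With
z = (r_AB − prediction)/SD (all four SDs in quadrature): synergistic if
z > 2, sub-additive if z < −2; otherwise additive when both single agents
are individually active at the same 2-SD standard, else null. "Null unless
both agents are active" is deliberate: a tight-binding context where
ataluren does nothing should not be called additive just because G418
works. The 2-SD thresholds are a convention, not an estimated quantity.

## ΔRE–K correlation

Spearman rank correlation (average ranks on ties) and OLS of ΔRE on K
(linear K by default; log K by configuration), pooled and stratified by
shape class. Detection-limited contexts enter at the 1 nM bound by default
(configurable to drop). Because the cooperative class lies on a lower,
shallower trend, pooling dilutes the correlation; the stratified
statistics are the informative ones, and the generator reproduces that
structure for every seed.

## smFRET dwell analysis

Events are located by threshold crossing, not HMM idealization: each
channel is lightly smoothed (3-frame boxcar), its low/high levels
estimated by 1-D two-means with a separation test (≥3.5 pooled
within-cluster SDs between means; a mean-split pure Gaussian scores ~2.7,
so noise-only channels are rejected rather than thresholded), and a state
change must persist ≥3 frames. A donor whose "low" level exceeds half its
high level is FRET-quenched, not photobleached, and the tRNA dwell is
censored. Arrival waits run injection → sustained acceptor appearance;
tRNA dwells FRET start → donor loss; factor dwells acceptor appearance →
acceptor loss. Censored dwells (trace ends while bound) are excluded from
rate estimation by default. Apparent rates are exponential ML estimates
(1/mean dwell, ≥20 uncensored dwells required) with percentile-bootstrap
95% CIs. FRET efficiency is the uncorrected proximity ratio
ΣA/(ΣA + ΣD) over the bound window — adequate for the ~0.25 regime this
assay reports, and no gamma/crosstalk calibration is simulated.

## Synthetic-data conditions

The generator defaults encode the study conditions end to end; all
randomness flows through one integer-seeded PCG64 stream, so outputs are
bit-reproducible.

| quantity | default | rationale |
|---|---|---|
| panel size / classes | 36 = 28 hyperbolic + 8 sigmoidal | survey composition emulated |
| k_cat | log-normal, median 0.173 min⁻¹, σ_log 0.335 | ~90% within 0.1–0.3 min⁻¹ |
| K, hyperbolic | log-uniform 1–35 nM (+2 at 0.5 nM) | ≥35-fold span; mean ≈ 9 nM |
| K, sigmoidal | log-uniform 15–50 nM | mean ≈ 28 nM; weaker engagement |
| titration design | 8 points, 0–120 nM RFC, P₅ = 50 nM | plate-reader titration range |
| k_obs noise | 10% relative (SE column emitted) | triplicate-level scatter |
| anisotropy noise | σ = 0.005 on 61 points over 30 min | plate-reader regime |
| ΔRE link | 0.6·K (hyperbolic); 0.15·K − 1 (sigmoidal); noise σ = 1.5 pp, floor 0 | increasing in K; cooperative class consistently lower |
| competition | TC 0.2 μM, RFC 50 nM, reference basal RE = 0.20 | assay calibration point |
| combination fixtures | effects 0.10–0.25, interaction 0.15–0.30, SD 0.02 | labels recoverable by construction at the 2-SD rule |
| smFRET | 0.1 s frames, injection at 10 s, 35 nM RFC; rates 0.10/0.12/0.10 s⁻¹; E = 0.25; per-channel SNR 5 | single-concentration dwell assay |

What the generator does *not* emulate: photophysics (blinking, bleaching
mid-dwell), baseline drift in plate-reader traces, day-to-day prep
variability, correlated replicate errors, any sequence→K mechanism (codon
identities are decorative labels on kinetic truths — the mechanistic cause
of the K spread is precisely what is not modeled), proofreading kinetics
of near-cognate accommodation, and nonsense-mediated decay. Passing
closed-loop tests therefore demonstrates estimator correctness under the
stated noise models, not robustness to those real-data effects.

## Problem sizes in the validation suite

Recovery statistics use 500 series per class in the test suite and 200 in
the acceptance script; combination accuracy pools 9 complexes × 200 (tests)
or × 100 (script) seeds; smFRET uses 500 traces for event detection and
2000 dwells per category for rate recovery; the solver is checked against
a 10⁻¹²-resolution bisection oracle on 10⁴ random conditions. These sizes
give Monte-Carlo error comfortably below the asserted tolerances.

## Known limitations

- K estimates for tight binders at standard complex concentrations are
  bound-limited and scatter ~two-fold per single series (see the
  identifiability caveat); treat single-series K_M below ~P₅/5 as
  order-of-magnitude.
- Each complex is fit independently; no hierarchical sharing of k_cat or
  noise across the panel.
- The additive null model for combinations is effect-additivity on the RE
  scale with a cap at 1 — other null models (Bliss independence, Loewe)
  would give different synergy calls near saturation.
- eRF3 is assumed saturating throughout and never modeled explicitly.
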
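# ptckin

Termination kinetics and readthrough analysis at premature termination
codons (PTCs), for mechanistic enzymology of eukaryotic translation
termination.

About 12% of human disease mutations create a PTC — a stop codon inside a
coding sequence. Readthrough-inducing drugs such as ataluren rescue
expression by letting a suppressor aminoacyl-tRNA decode the stop codon
before the release factor complex (RFC, eRF1·eRF3·GTP) terminates. How well
that works depends strongly on the mRNA sequence context around the stop
codon, because context modulates how avidly the RFC engages the
pretermination ribosome. This package implements the quantitative analysis
chain that turns in vitro measurements on defined pretermination complexes
("Stop-POST5": a ribosome carrying a 5-residue peptidyl-tRNA with the stop
codon in the A site) into that mechanistic picture:

- **Anisotropy decays → release rates.** Fluorescence-anisotropy time
  courses of labeled peptide release are fit to a single exponential with
  an asymptote (or a biphasic form where required; the fast phase is the
  reported rate), giving the observed termination rate k_obs.
- **Depletion-corrected titrations.** k_obs versus RFC follows the Hill
  rate law

      k_obs = k_cat · RFC_free^n / (RFC_free^n + K^n),   n ∈ {1, 2}

  where n = 1 is Michaelis–Menten (half-saturation constant K_M^RFC,
  hyperbolic titration) and n = 2 captures positive cooperativity
  (K_A^RFC, S-shaped titration). Because complexes are titrated at
  concentrations comparable to K, bound RFC depletes the free pool; the
  free concentration is recovered from mass balance
  (K^n·RP₅ = RFC_free^n·P₅_free with RFC_free = RFC_total − n·RP₅,
  P₅_free = P₅_total − RP₅ — a quadratic for n = 1 solved in closed form,
  a cubic for n = 2 solved by bracketed root finding) self-consistently
  inside the nonlinear fit. Shape classification uses an
  extra-sum-of-squares F-test; fitted K ≤ 1 nM is flagged as
  detection-limited.
- **Readthrough efficiency (RE).** Both assay formats (³H co-sedimentation
  stoichiometry and the fluorescence change ΔF at 2 min) are normalized to
  the cognate full-readthrough control, landing on a common 0–1 scale.
  The kinetic competition at the A site is modeled as
  p_rt = a·[TC] / (a·[TC] + k_term), with ataluren scaling K by
  (1 + [ataluren]/K_i) (competitive inhibition of termination) and G418
  multiplying the productive ternary-complex association rate.
- **ΔRE vs K correlation.** The ataluren-induced gain in readthrough
  (ΔRE, percentage points at 1 mM) is correlated with K by Spearman rank
  and OLS, pooled and stratified by titration shape.
- **Combination classification.** Two-agent treatments (ataluren × G418,
  ataluren × ACE-tRNA) are scored against an additive null model; the
  standardized excess z yields null / additive / synergistic /
  sub-additive verdicts.
- **smFRET dwell rates.** Two-color single-molecule traces (donor-labeled
  P-site tRNA, acceptor-labeled RFC under alternating-laser excitation)
  are segmented by two-state thresholding into arrival and bound dwells;
  apparent rates are maximum-likelihood exponential estimates with
  bootstrap CIs, plus the proximity-ratio FRET efficiency.

No raw experimental data are distributed; a fully seeded synthetic-data
generator (`ptckin.simulate`) produces every input kind with recorded
ground truth, so the whole chain runs and is validated closed-loop.

## Worked example

The analysis is organized as numbered drivers over the library:

```sh
python analysis/01_simulate_panel.py --seed 0
python analysis/02_fit_termination.py
python analysis/03_readthrough_combinations.py --seed 0
python analysis/04_correlate.py
python analysis/05_smfret_rates.py --seed 0
```

which prints:

```
panel: 36 contexts (28 hyperbolic / 8 sigmoidal), 2 at the <=1 nM limit
K spans 39-fold above the limit; k_cat 97% within 0.1-0.3 min^-1
fit 36 complexes: 28 hyperbolic, 8 sigmoidal (shape recovery 100%)
3 complexes flagged at the <=1 nM detection limit
readthrough for 36 contexts: basal RE 0.04-0.31, ΔRE -0.3-19.9 pp
combination verdicts: 3 synergistic, 2 additive, 3 null (label recovery 89%)
pooled: Spearman r = 0.43 over 36 contexts (OLS slope 0.15 pp/nM)
  hyperbolic: r = 0.51, n = 28, mean K = 13.8 nM, mean ΔRE = 7.4 pp
  sigmoidal : r = 0.45, n = 8, mean K = 34.7 nM, mean ΔRE = 4.6 pp
k_arrival_app: 0.106 /s  (95% CI 0.094-0.118)
k_dis_tRNA_app: 0.100 /s  (95% CI 0.090-0.114)
k_dis_eRF1_app: 0.102 /s  (95% CI 0.092-0.115)
FRET efficiency E = 0.249 (289 arrivals from 300 traces)
```

Reading this: every generated titration shape is recovered (28/8), basal
readthrough spans a realistic range with the reference context calibrated
to 20%, ΔRE rises with fitted K (per-class trends stronger than the pooled
one, since the cooperative class responds less per unit K), and the
single-molecule estimators recover the generative rates (0.10–0.12 s⁻¹)
and FRET efficiency (0.25). Tables land under `results/`. The same chain
is available as a CLI (`ptckin simulate|fit-decay|fit-titration|
readthrough|correlate|smfret|run`) and as one call,
`ptckin.pipeline.run_pipeline`, which is byte-reproducible under a fixed
seed.

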
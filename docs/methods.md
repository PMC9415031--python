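# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline, and what the synthetic-data generators do and do
not emulate.

## JIP-test (`phycotox.ojip`)

**Model.** The fast fluorescence induction of a dark-adapted sample is
summarized by its cardinal points — O (50 µs), K (300 µs), J (2 ms),
I (30 ms) and the peak P — and by the complementary area between the curve
and FM. The derivations are the standard JIP-test algebra: with
FV = FM − F0,

| quantity | formula |
| --- | --- |
| relative variable fluorescence | V_X = (F_X − F0)/FV for X ∈ {K, J, I} |
| initial rise slope | M0 = 4·(F300 − F0)/FV (ms⁻¹; 4 = 1/0.25 ms) |
| complementary area | ∫(FM − F(t))dt from the O step to t(FM), trapezoidal |
| normalized areas | S_M = area/FV, S_S = V_J/M0, N = S_M/S_S |
| quantum yields | φP0 = FV/FM, ψ0 = 1 − V_J, φE0 = φP0·ψ0, δR0 = (1 − V_I)/(1 − V_J) |
| fluxes per CS | ABS/CS (proxy), TR = φP0·ABS, ET = φE0·ABS, DI = ABS − TR |
| RC density | RC/ABS = φP0·(V_J/M0), γ_RC = (RC/ABS)/(1 + RC/ABS) |
| performance ratios | TR0/DI0 = φP0/(1 − φP0), ψ0/(1 − ψ0), δR0/(1 − δR0) |
| PSI end-acceptor flux | RE0/RC = M0·(1/V_J)·(1 − V_I) |
| OEC fraction | [1 − V_K/V_J]_sample / [1 − V_K/V_J]_control-mean |

**Conventions and open points.**

* Cardinal step times are configuration, defaulting to common fluorometer
  firmware values (50 µs / 300 µs / 2 ms / 30 ms); instruments differ, so
  all step times are per-dataset settings.
* ABS/CS uses F0 (the "CS0" convention) by default; a single switch
  (`cross_section="FM"`) selects the CSM convention and every per-CS flux
  inherits it.
* Two distinct "dark-reaction" ratios are reported: `psiRatio`
  = ψ0/(1 − ψ0) and `kEq` = ψE0/(1 − ψE0) **with ψE0 ≡ φE0**. In the
  classical single-definition JIP-test ψ0 and ψE0 coincide (both 1 − V_J),
  which would make the two ratios identical; pipelines in this field
  nevertheless report them as separate quantities, so the equilibrium-constant
  variant is computed from the full electron-transport yield φE0 here. This
  is a documented package convention, not a claim about any particular
  instrument's firmware.
* The oxidized-quinone-pool proxy `qPool` is reported as S_M (the
  area-normalized pool measure); no separate formula exists in the JIP
  literature for it.
* Degenerate ratios (V_J ∈ {0,1}, V_I = V_J, φP0 = 1 …) yield NaN with a
  warning, never an exception or an infinity, so cohort statistics see
  explicit missingness.
* Numerical choices stated for bit-reproducibility: linear interpolation for
  cardinal points; trapezoidal integration for the area (the O-step and
  t(FM) endpoints are included by interpolation); all times in µs, areas
  converted to a.u.·ms.

**Connectivity (grouping probability).** Excitonic connectivity between PSII
units makes the O–J rise sigmoidal. The estimator fits the relative rise
W(t) = (F − F0)/(FJ − F0), measured from the O step, with

    W = s·(1 + C)·E/(1 + C·E) + m·(t − t_O),   E = 1 − exp(−k·(t − t_O))

by bounded least squares (multi-start over k and C; s ∈ [0.5, 2], m ≥ 0) and
reports p_G = C/(1 + C). The two nuisance parameters matter: *s* absorbs the
~0.1 % normalization error from FJ sitting below the fast-phase asymptote,
and *m* absorbs the quasi-linear onset of the slower I/P phases inside the
O–J window. Without them the estimator is biased by ~0.03 (s) and up to
~+0.25 on complete transients (m). On a pure hyperbolic rise both fit to
their neutral values and C is recovered exactly; on complete noiseless
three-phase transients the residual p_G bias is below 0.02. A negative
fitted C is clipped to 0 with a warning; non-convergence returns NaN. The
exact formula behind commercial instruments' grouping output is not public;
this fit is the package's documented estimator.

## Rapid light curves (`phycotox.rlc`)

The exponential saturation model with photoinhibition (Platt-type) is used:
rETR(E) = Ps·(1 − e^(−αE/Ps))·e^(−βE/Ps). α is the light-limited slope,
rETRmax the analytic maximum (Ps·(α/(α+β))·(β/(α+β))^(β/α) for β > 0, Ps
otherwise) and Ek = rETRmax/α. Fitting is bounded (all parameters ≥ 0)
`curve_fit` with tolerances 1e-8 and a fixed data-driven multi-start grid
(α from the first two light steps ×{1,2}; Ps from the maximum rETR ×{1,2};
β ∈ {~0, α/100, α/10}), lowest-RSS start wins — deterministic by
construction. A reduced β = 0 model is a config switch. The model family is
a package choice: the parameter set (α, rETRmax, Ek, β) uniquely points to
this formulation, but other saturation functions exist.

## LIF features (`phycotox.lif`)

Chlorophyll emission is reduced to the red (650–700 nm) and far-red
(700–760 nm) window maxima with three-point parabolic refinement (exact for
a quadratic peak on a uniform grid), and the red/far-red ratio. The ratio is
formed from the detected maxima by default — matching reports that quote
band maxima near 681/731 nm while naming the ratio F680/F735 — with a
`fixed` mode (interpolated intensities at exactly 680 and 735 nm) as the
alternative, since which convention a given study used is usually unstated.
Smoothing is off by default for reproducibility. Boundary-pinned or flat
windows are flagged, and the ratio is still computed from boundary values
with a warning.

## Gauss-peak pigment deconvolution (`phycotox.pigments`)

The absorbance spectrum (350–750 nm, uniform grid) is modeled as a
non-negative linear combination of pigment templates plus an unconstrained
affine baseline (turbidity drift), solved by bounded-variable least squares
(`lsq_linear`, method BVLS). Coefficients convert to extract concentration
via each pigment's specific absorption coefficient and the path length, then
to tissue content via extract volume / extracted fresh mass; all three
representations are kept in the result for audit.

The shipped registry covers the ten pigments of green-macroalgal extracts.
Band centers follow standard in-acetone absorption maxima. A deliberate
design point: the five 400–500 nm carotenoid/xanthophyll templates differ in
*vibronic resolution* (band width and amplitude ratio), not just position —
lutein and violaxanthin sharply resolved, β-carotene strongly smeared,
zeaxanthin intermediate. Conditioning analysis during design showed that
with equal-width carotenoid bands the Soret-region columns are nearly
collinear and a small lutein pool (~3 µg·g⁻¹ against ~56 µg·g⁻¹
chlorophyll a) is unrecoverable at 1 % measurement noise (variance-inflation
factor ≈ 4.4; differentiated widths bring it to ≈ 0.45). Real spectral
libraries earn their conditioning the same way. The registry is data, not
code: laboratory calibrations can replace it wholesale, and the generator
and the fitter always share whichever registry is supplied, so recovery
tests are self-consistent. A condition number above 1e4 triggers a warning
naming the most collinear template pair. Tissue contents are normalized per
fresh weight, matching how such pigment tables are usually reported.

## Biochemical calculators (`phycotox.biochem`)

* **Slope assays** (APX, CAT, GR): activity = |dA/dt|/(ε·l) · V · dilution /
  protein, with defaults ε(APX) = 2.8 mM⁻¹cm⁻¹ at 290 nm, ε(CAT) =
  39.4 M⁻¹cm⁻¹ at 240 nm, ε(GR) = 6.22 mM⁻¹cm⁻¹ at 340 nm. The regression
  window defaults to the full trace; an automatic mode selects the longest
  window with R² ≥ 0.98, ties broken to the earliest window
  (deterministic). A slope of the wrong sign gives zero activity with a
  warning; low R² flags the record.
* **SOD**: percent inhibition of pyrogallol autoxidation against the
  no-extract blank, 100·(1 − slope_sample/slope_blank); 1 U = 50 %
  inhibition, per mg protein. Both the %-inhibition and the unit value are
  emitted since reporting conventions differ.
* **MDA**: (A532 − A600)/(155 mM⁻¹cm⁻¹·l), scaled by dilution; negative
  corrected absorbance → 0 with a warning; also expressed per g FW.
* **DBI**: Σ weight(class)·%/100 with class weights (monoene **2**, diene 2,
  triene 3, tetraene 4, pentaene 5) — the `paper` convention implemented as
  printed in this line of work; the common literature convention (monoene
  weight 1 = the true double-bond count) is available as
  `convention="classic"`. SFA/UFA and PUFA/SFA accompany the index.
* **Energy budget**: Ea = 17 500·carb + 24 000·prot + 39 500·lip
  (mJ·mg⁻¹ FW); ETS → Ec via 2 µmol INT-formazan per µmol O₂ and
  480 mJ·µmol⁻¹ O₂; CEA = Ea/Ec (NaN when Ec = 0). Assay interval and
  volume factors are configuration, as they vary between protocols.

All calculators are homogeneous of degree 1 in their raw signal.

## Statistics (`phycotox.stats`)

**Rank-based comparison.** Tie-corrected Kruskal–Wallis; when the omnibus
test rejects at α, all pairs are compared on mean ranks with Fisher's LSD
criterion at the Bonferroni-adjusted level α/C(k,2):

    |R̄_i − R̄_j| > t_{1−α'/2, N−k} · sqrt( S²·(N−1−H)/(N−k)·(1/n_i + 1/n_j) )

with S² the pooled rank variance (tie-averaged ranks). Letters come from the
insert-and-absorb compact-letter-display algorithm, assigned alphabetically
in dose order — deterministic given the input ordering. Gating the post hoc
on the omnibus test keeps the family-wise behavior of the display simple
(single shared letter whenever the gate fails) and is verified by simulation
to hold the nominal type-I rate.

**Discriminant classification.** Features (scalar endpoints or whole curves
on a common grid) are standardized per dimension; when dimensionality ≥
sample count a deterministic variance-ranked principal-component reduction
(full SVD, default 10 components) precedes the discriminant fit — curve
datasets have hundreds of grid points against 18–30 replicates per group, so
unreduced scatter matrices would be singular. Both resubstitution and
leave-one-out accuracies are reported; leave-one-out refits the entire
pipeline (scaler, reduction, discriminant) in every fold and is the headline
figure, the conservative choice when a study does not state which accuracy
it quotes. A singular within-class scatter triggers a shrinkage (lsqr/auto)
refit, noted in the result. Group ellipses come from each group's 2-D
projection covariance (semi-axes = sqrt of eigenvalues, i.e. 1 s.d.).

## Synthetic data (`phycotox.synthetic`)

The generators emulate a six-treatment (0/10/50/100/250/500 µg·L⁻¹) design
with the replicate structure of the assays: 18 transients, 30 emission
spectra, 3 pigment/enzyme/fatty-acid/peroxidation extracts and 5 energy
replicates per treatment. All randomness descends from one root seed through
named substreams (one per cohort), so cohorts are independent and every run
is reproducible; each generator stores per-sample ground truth.

* **Transients**: F(t) = F0 + FV·Σ wᵢ·(1 − e^(−(t−t_O)/τᵢ)) with three
  phases (τ ≈ 0.3/7/80 ms); weights are solved so the relative variable
  fluorescence hits the target V_J and V_I exactly at the J and I times, and
  the fast phase is distorted by the connectivity hyperbola with the
  treatment's C. Sampling is log-spaced 10 µs–300 ms with the nominal step
  times included exactly (as instrument protocols do). Stored truth S_M is
  computed by dense (2·10⁴-point) integration of the closed form — the
  independent oracle for the trapezoidal estimate. A separate
  `connectivity_transient` builds curves whose O–J window is *exactly* the
  hyperbola (slow phases start at the J step), the uncontaminated oracle for
  the connectivity fit.
* **Default effect profiles** encode the qualitative dose-response pattern
  the pipeline targets: photochemical suppression strongest at 250 µg·L⁻¹
  with partial recovery at 500, near-control behavior at 10, intermediate
  suppression at 50–100, rising connectivity-disruption with dose. These are
  illustrative, editable defaults — not claims about real tissue beyond the
  published group means used as anchors (red/far-red ratio means
  41.12/37.25/103.63/73.45/53.78/70.80 and red-peak positions per treatment;
  the 6×10 pigment target matrix, e.g. control chlorophyll a 56.03 and
  chlorophyll b 38.90 µg·g⁻¹ FW with antheraxanthin 0, rising to
  3.81 µg·g⁻¹ at the highest dose).
* **Emission spectra** are two Gaussians (red ≈ 681 nm, far-red ≈ 731 nm).
  The red band is given σ = 5.5 nm: with ratios of 40–100 a broader red band
  would bury the far-red maximum under its own tail at the 700 nm window
  edge, making the far-red peak wavelength undetectable (plausibly why
  real far-red peak positions scatter by ±9 nm). Between-sample ratio CV is
  0.45, matching the published dispersion for this design — with the
  consequence that group means of n = 30 samples sit within ~8 % (1 SEM) of
  target, not arbitrarily close.
* **Noise** is multiplicative Gaussian everywhere (signals are positive),
  truncated away from zero; biological variability enters at the parameter
  level (per-sample jitter of amplitudes, efficiencies, targets),
  measurement noise at the per-point level.
* **Not emulated**: instrument-specific noise spectra, detector saturation,
  baseline wander of real fluorometers, kinetic heterogeneity beyond three
  exponential phases, chromatogram-level fatty-acid data (percent tables are
  generated directly), and any mechanistic PSII electron-transport kinetics.
  Passing round-trip tests therefore demonstrates correctness of the
  *estimators* under the stated noise model, not robustness to every
  artifact of real instruments.

A `null_config` helper flattens every effect profile (noise unchanged) for
type-I-error and null-pipeline checks.

## Pipeline (`phycotox.pipeline`, CLI)

One structured configuration drives simulate → JIP/RLC/LIF/pigments/biochem
→ letters + discriminant classification. Outputs are CSV/JSON only, with
fixed float formatting (`%.10g`) and no timestamps; the manifest records the
config hash, seed, stage outputs and collected warnings. Reruns with the
same config and seed are byte-identical, manifest included. Any stage error
aborts with the stage name; a stage subset can be run over precomputed
inputs, with skipped stages noted in the manifest.

## Problem sizes

Default analyses and the reproduction script use the full design
(6 × 18 transients, 6 × 30 spectra, …); simulation-based checks use
100 seeds for pigment-noise recovery, 200 for light-curve noise recovery,
1000–2000 null datasets for the Kruskal–Wallis calibration, and 4–6 label
permutations for the chance-level discriminant check — sizes chosen so each
estimate's Monte-Carlo error is comfortably below the property being
asserted.

## Known limitations

* The connectivity estimator's residual bias (< 0.02 noiseless) grows with
  per-point noise; per-sample p_G on noisy transients scatters visibly
  (±0.05–0.1) even though cohort means are stable.
* The rank-LSD post hoc is powerful but, like its parametric namesake,
  liberal pairwise; the Bonferroni adjustment and the omnibus gate are what
  control the family-wise rate here.
* Six-class discriminant accuracy on the default synthetic design is ~0.65
  (leave-one-out): treatments within the same imposed shape grouping are
  nearly identical by construction, so only the three groupings separate
  cleanly (grouping-level accuracy ≥ 0.8). Real datasets with richer
  per-treatment structure can classify better at the treatment level.
* GPS recovery quality is a property of the template library's conditioning;
  swapping in a poorly conditioned laboratory library will degrade minor
  pigments first (the condition-number warning exists for exactly this).
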
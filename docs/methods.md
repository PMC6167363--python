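# Methods

`dimlight` quantifies whether a visual pigment behaves like a rod
(dim-light) pigment along three independent axes: the thermal activity
of its chromophore, its thermal stability as a protein, and the position
of its gene among the visual-opsin families. Everything below is
computed by the package itself; the test suite and `scripts/acceptance.py`
recompute every number quoted here from scratch.

## 1. Thermal isomerization rate of the chromophore

### Model

A pigment in darkness is described by a two-step scheme: the inactive
pigment R converts spontaneously to the signalling state R\* when its
11-*cis* retinal chromophore isomerizes thermally (rate constant
`k_th`, s⁻¹), and R\* decays with rate constant `k_d` (s⁻¹). At the
dark steady state the rate of G-protein activation per mole of pigment
(`v_dark`) relates the per-R\* activation rate (`v_light`) to the two
constants, giving

```
k_th = (v_dark / v_light) · k_d
```

The three measured quantities come from three assays, each fitted with a
single exponential:

* **Dark G-protein activation** (`gtpgs_dark`): GTPγS uptake in
  darkness. Two samples are measured — the pigment regenerated with
  native 11-*cis* retinal (`pigment_n`) and a control regenerated with a
  7-membered-ring locked retinal (`pigment_7mr`) that cannot isomerize.
  `v_dark` is the difference of their initial rates, paired by
  replicate.
* **Flash-induced activation** (`fluor_light`): G-protein tryptophan
  fluorescence rise after a flash, with and without G protein;
  `v_light` is the difference of initial rates.
* **Retinal release** (`retinal_release`): decay of pigment tryptophan
  fluorescence as the chromophore leaves the bleached pigment; the
  fitted rate is `k_d`.

The *initial rate* of a fitted exponential `A(1 − e^(−kt)) + c` is its
t→0 derivative `A·k`, not a finite-difference slope: `A·k` is the
identifiable combination even when the trace is so shallow that `A` and
`k` are individually ill-determined, which is exactly the regime of the
dark assay for stable pigments.

### Fitting

For fixed `k` the exponential models are linear in `(A, c)`, so the fit
profiles the linear parameters out analytically and minimizes the
residual sum of squares over `log k` with bounded Brent search
(`k ∈ [10⁻⁴/T, 10/Δt_min]` for a trace of span `T` and minimum step
`Δt_min`). This is immune to the `(A, k)` ridge that makes generic
3-parameter Levenberg–Marquardt slow and fragile on nearly-linear
traces. Parameter covariance is reconstructed from the full Jacobian at
the optimum. A trace whose signal range is below 10 machine epsilons of
its absolute mean raises `DegenerateSignal` — a zero-rate exponential is
unidentifiable in `(A, k)`, so no zero estimate is fabricated.

### Error propagation and comparison

Means `M` and standard errors of the mean `ε` are taken across
replicate-level estimates (4 replicates by default), and combined by
first-order propagation:

```
M_th = (M_dark / M_light) · M_d
ε_th = M_th · sqrt((ε_dark/M_dark)² + (ε_light/M_light)² + (ε_d/M_d)²)
```

The identity `M_th · M_light = M_dark · M_d` holds exactly by
construction and is asserted property-style in the tests. A negative
`v_dark` estimate is reported with a flag, never clipped, because
clipping would bias the propagation. Pigments are compared through
relative rate constants with a two-tailed pooled-variance (Student)
t test on replicate-level `k_th` values; significance threshold 0.05.

### Synthetic assay conditions

The generator's defaults define the simulated study conditions:

| quantity | default | rationale |
|---|---|---|
| `k_d` | 10⁻³ s⁻¹ | active-state half-life ≈ 12 min at 37 °C |
| `v_light` | 5·10⁻³ signal·s⁻¹ | flash response saturating in ~3 min |
| `k_th` | 4·10⁻⁵ s⁻¹ | follows from the steady-state identity with `v_dark` = 2·10⁻⁴ |
| background dark rate | 2·10⁻⁵ s⁻¹ | 10 % of `v_dark`, the 7mr control level |
| noise sd | 2 % of plateau | per assay, additive Gaussian |
| replicates | 4 | "more than three independent measurements" |
| time grids | 0–1200 s ×13 / 0–600 s ×61 / 0–3600 s ×37 | resolves the default rates |

For fold-ratio experiments between a slow rod-like and a 20- or 200-fold
faster cone-like pigment, each pigment's time grids are rescaled so its
own exponentials span ~2.5 time constants (`adapted_time_grids`), as an
experimenter configures acquisition per sample; with the default grids a
200-fold faster pigment would saturate between the first two samples.

What the generator does **not** emulate: shot noise on radioactive
counts, instrument dead time, photobleaching during fluorescence
acquisition, or pigment-to-pigment differences in plateau amplitude.
Passing tests therefore demonstrate correctness of the estimators under
additive Gaussian noise, not robustness to every laboratory artifact.

## 2. Thermal stability from absorbance spectra

Absorbance curves follow the Govardovskii A1-pigment template (α and β
bands); the α-band peak position `λmax` is estimated by least squares
with free scale and baseline, scanning `λmax` on a 0.1 nm grid over the
fitting window (default 400–650 nm) and refining by bounded
minimization. The estimate is invariant under affine transforms of the
absorbance axis, and a `FlatSpectrum` error is raised when the fitted
band is smaller than 3× a robust noise floor (median absolute deviation
of first differences / √2). A raw-argmax mode exists for curves that do
not follow the template.

Thermal decay is quantified from paired spectra at each 37 °C
incubation time: a dark spectrum and a post-bleach spectrum
(hydroxylamine + yellow light removes the pigment band, converting the
chromophore to retinal oxime absorbing near 360 nm). Their difference
isolates the pigment remaining at time t; it is read at 540 nm — on the
long-wave flank, clear of the oxime band — and normalized by the t = 0
value. The reading averages over a 10 nm band around the read
wavelength, emulating monochromator bandwidth; a single 1 nm grid point
would be needlessly noise-limited. The residual fractions are fitted by
one-parameter first-order decay `e^(−kt)`; the reported interval is the
±1.96 SE Wald interval. A zero-decay pigment yields fractions
identically 1 — the "quite stable" rhodopsin limit.

Synthetic decay series default to a 0.1 AU peak, 0.002 AU spectral
noise, and 6–7 timepoints spanning about two half-lives.

## 3. Exhaustive topology evaluation

### Likelihood engine

Amino-acid alignments are scored on fixed unrooted topologies by
Felsenstein pruning under a reversible empirical model. The JTT
exchangeabilities and frequencies ship with the package
(`data/jtt.dat`, the standard published values); any 20×20 symmetric
table (e.g. a transmembrane-specific variant) can be supplied as a
PAML-style file. The rate matrix is normalized to one expected
substitution per unit branch length; transition matrices come from a
symmetrized eigendecomposition. Among-site rate variation uses Yang's
discrete-gamma model: k equal-probability categories (default 4), each
category's rate equal to the mean of the mean-one gamma density over its
inter-quantile slice, computed via the incomplete-gamma identity and
verified against direct quadrature. Ambiguous residues (X, B, Z, gaps)
contribute all-ones tip partials, i.e. are marginalized.

Correctness anchors: pruning equals brute-force summation over
internal-node states on quartets to <10⁻¹⁰; per-site log-likelihoods
are invariant under re-rooting; totals agree with an independent
phylogenetics engine (phangorn's `pml`, same model settings) to
10 decimal places on a frozen synthetic dataset.

### Branch lengths, shape, enumeration

Branch lengths are optimized coordinate-wise: for each edge, directed
conditional-likelihood messages are cached for the rest of the tree, so
the 1-D bounded search over that edge's length costs one transition
matrix per category per evaluation. Cycles repeat until the total lnL
improves by <10⁻⁶; lengths are bounded to [10⁻⁸, 20]
substitutions/site. The gamma shape α is optimized (bounded in
[0.02, 100]) by alternating with branch lengths on one topology.

All unrooted binary topologies over n effective units (3 ≤ n ≤ 8,
counts (2n−5)!!) are enumerated by stepwise addition in deterministic
order. A fixed rooted subtree (e.g. `(((RH1,RH2),SWS2),SWS1)`) is
treated as a single unit during enumeration and grafted back intact, so
six free OTUs give 105 topologies and four free tips plus one fixed
subtree give 15.

`exhaustive_ml` with `alpha="auto"` finds the ML topology at α = 1,
optimizes α there, then re-scores every topology with that single fixed
α — mirroring the convention of reporting one optimized shape per
analysis. Branch lengths are re-optimized per topology.

### Topology tests

All tests operate on the per-site log-likelihood matrix by RELL
resampling (sites resampled with replacement; no re-optimization), the
standard CONSEL-style practice. Ties for "best topology in a replicate"
are split uniformly at random (seeded), so bootstrap proportions sum
to 1.

* **KH** — replicate lnL differences between two topologies, centered at
  their own mean; two-sided by default (one-sided available).
* **SH** — each topology centered at its own replicate mean; null
  statistic `max_k(centered_k) − centered_t`; corrects for selecting the
  ML topology and is conservative.
* **AU** — multiscale bootstrap: bootstrap proportions BP(r) at 10
  scales r = 0.5…1.4 (default B = 10 000 per scale) are fitted by
  `Φ⁻¹(1−BP(r)) = d√r + c/√r` via maximum likelihood on the binomial
  counts (weighted least squares provides the start and the fallback);
  `p_AU = 1 − Φ(d − c)`. Topologies with BP ∈ {0, 1} at every scale get
  p ∈ {0, 1} with a degeneracy flag.

Calibration, verified on exchangeable-null matrices (equal column
means): KH and AU type-I error at the 5 % level fall in [0.03, 0.07];
SH stays at or below nominal. On shared replicates the SH p-value
dominates the **one-sided** KH p-value pointwise (the SH max-statistic
is never smaller than the single ML-vs-candidate difference); with the
two-sided KH default this dominance holds typically but is not a
theorem, which is why the dominance check is stated one-sided.

### Problem sizes

Exhaustive scans in the tests use 4–5 taxa (3–15 topologies) at 100–300
sites, and the acceptance script runs the full six-OTU scan (105
topologies, 290 sites, α estimated from the data) plus calibration
batches of 1000–1200 null matrices — sizes chosen so the whole pipeline
re-runs comfortably on a laptop-class single core. Simulation-based
recovery statements (e.g. the generating topology is recovered as ML)
are exercised at these sizes; they are consistency checks, not power
analyses.

## Known limitations

* The kinetic scheme is the simplified two-step model; multi-exponential
  or Michaelis–Menten behaviour is out of scope by design.
* The spectral module models bleaching as complete removal of the
  pigment band; photoproduct absorbance is assumed negligible at the
  read wavelength rather than modelled.
* The likelihood engine is exhaustive-only (≤ 8 effective tips); there
  is no heuristic tree search, no codon/nucleotide models, and no
  alignment construction.
* RELL is an approximation to full per-replicate re-optimization; a
  `mode="full"` bootstrap exists for small problems but is not the
  default.
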
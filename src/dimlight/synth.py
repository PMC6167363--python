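"""Synthetic ground-truth generators for every pipeline input.

The kinetic generator emulates a two-step activation scheme for a visual
pigment: the inactive pigment R converts to the signalling state R* by
thermal isomerization of its 11-cis retinal chromophore at rate ``k_th``,
and R* decays at rate ``k_d``.  Three assays observe it:

* ``gtpgs_dark`` — GTPgammaS uptake by the G protein in darkness.  The
  sample regenerated with native retinal ("pigment_n") accumulates signal
  whose initial rate is ``v_dark`` plus a background; the control
  regenerated with a 7-membered-ring locked retinal ("pigment_7mr")
  cannot isomerize and shows background only.
* ``fluor_light`` — G-protein tryptophan fluorescence after a flash;
  the sample with G protein rises at ``v_light`` above the one without.
* ``retinal_release`` — pigment tryptophan fluorescence as retinal leaves
  the bleached pigment, decaying single-exponentially at ``k_d``.

At steady state in the dark ``v_dark = k_th * v_light / k_d``, so the
three measured quantities invert to ``k_th``.

The spectral generator produces A1-pigment absorbance curves on the
Govardovskii template with first-order loss of pigment during incubation,
plus a paired post-bleach spectrum (hydroxylamine + yellow light removes
the pigment band).  The sequence generator evolves amino-acid sites on a
known tree under any reversible model with discrete-gamma rates, and a
null generator produces exchangeable site-likelihood matrices for test
calibration.  All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyMatrix, InvalidLambdaMax, InvalidRates
from .io import Alignment, Spectrum, TimeCourse, Topology
from .phylo import GammaRates, SiteLikelihoodMatrix, SubstitutionModel

# Default assay time grids (seconds): chosen to resolve the default rates
# below with laboratory-realistic sampling density.
DEFAULT_TIMES = {
    "gtpgs_dark": np.linspace(0.0, 1200.0, 13),
    "fluor_light": np.linspace(0.0, 600.0, 61),
    "retinal_release": np.linspace(0.0, 3600.0, 37),
}

#: replicates per assay; "at least three independent measurements" plus one
DEFAULT_REPLICATES = 4


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth rates for one pigment.

    ``v_dark_true`` is derived, not free: the steady-state identity
    ``v_dark = k_th * v_light / k_d`` ties the three assays together.
    Signal units are arbitrary (bound fraction / relative fluorescence);
    rates are per second.
    """

    k_th_true: float = 4e-5
    k_d_true: float = 1e-3
    v_light_true: float = 5e-3
    #: saturation amplitude per assay, signal units
    plateaus: dict = field(
        default_factory=lambda: {
            "gtpgs_dark": 1.0,
            "fluor_light": 1.0,
            "retinal_release": 1.0,
        }
    )
    #: spontaneous (pigment-independent) initial rate in the dark assay
    background_rate: float = 2e-5
    #: initial rate of the fluorescence drift without G protein
    fluor_background_rate: float = 5e-4
    #: constant offset on the retinal-release trace
    release_offset: float = 0.1

    def __post_init__(self):
        for name in ("k_th_true", "k_d_true", "v_light_true"):
            v = getattr(self, name)
            if not (v > 0) or not np.isfinite(v):
                raise InvalidRates(f"{name} must be positive, got {v}")
        if self.background_rate < 0 or self.fluor_background_rate < 0:
            raise InvalidRates("background rates must be >= 0")

    @property
    def v_dark_true(self) -> float:
        return self.k_th_true * self.v_light_true / self.k_d_true

    def with_k_th(self, k_th: float) -> "KineticTruth":
        return replace(self, k_th_true=k_th)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise, one sd per assay, plus spectral noise."""

    assay_sd: dict = field(
        default_factory=lambda: {
            "gtpgs_dark": 0.02,
            "fluor_light": 0.02,
            "retinal_release": 0.02,
        }
    )
    spectral_sd: float = 0.002  # AU
    drift_amplitude: float = 0.0  # AU, slow spectral baseline drift
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.assay_sd.values()) or self.spectral_sd < 0:
            raise InvalidRates("noise sds must be >= 0")

    def rng(self, offset: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed + offset) % 2**31)


@dataclass(frozen=True)
class EvolModel:
    """Evolutionary simulation settings: a reversible substitution model
    plus discrete-gamma rate heterogeneity."""

    model: SubstitutionModel
    rates: GammaRates


# ---------------------------------------------------------------------------
# Kinetic assay bundles
# ---------------------------------------------------------------------------

def _rise(times, initial_rate, plateau):
    """Exponential saturation A(1 - e^(-kt)) with A*k = initial_rate."""
    if initial_rate <= 0:
        return np.zeros_like(times)
    k = initial_rate / plateau
    return plateau * (1.0 - np.exp(-k * times))


def gen_assay_bundle(
    truth: KineticTruth,
    noise: NoiseModel,
    n_replicates: int = DEFAULT_REPLICATES,
    times: dict | None = None,
) -> list[TimeCourse]:
    """Simulate all three assays for one pigment.

    Returns TimeCourse objects for every (assay, condition, replicate):
    ``gtpgs_dark`` x {pigment_n, pigment_7mr}, ``fluor_light`` x
    {with_Gt, without_Gt}, and ``retinal_release`` x {plain}.
    Deterministic for a given ``noise.seed``.
    """
    if n_replicates < 1:
        raise InvalidRates("need at least one replicate")
    grids = dict(DEFAULT_TIMES)
    if times:
        grids.update({k: np.asarray(v, dtype=float) for k, v in times.items()})
    rng = noise.rng()
    out = []

    t = grids["gtpgs_dark"]
    A = truth.plateaus["gtpgs_dark"]
    sd = noise.assay_sd["gtpgs_dark"]
    for rep in range(1, n_replicates + 1):
        clean_n = _rise(t, truth.v_dark_true + truth.background_rate, A)
        clean_b = _rise(t, truth.background_rate, A)
        out.append(TimeCourse("gtpgs_dark", "pigment_n", rep, t,
                              clean_n + rng.normal(0, sd, t.size)))
        out.append(TimeCourse("gtpgs_dark", "pigment_7mr", rep, t,
                              clean_b + rng.normal(0, sd, t.size)))

    t = grids["fluor_light"]
    A = truth.plateaus["fluor_light"]
    sd = noise.assay_sd["fluor_light"]
    for rep in range(1, n_replicates + 1):
        clean_w = _rise(t, truth.v_light_true + truth.fluor_background_rate, A)
        clean_o = _rise(t, truth.fluor_background_rate, A)
        out.append(TimeCourse("fluor_light", "with_Gt", rep, t,
                              clean_w + rng.normal(0, sd, t.size)))
        out.append(TimeCourse("fluor_light", "without_Gt", rep, t,
                              clean_o + rng.normal(0, sd, t.size)))

    t = grids["retinal_release"]
    A = truth.plateaus["retinal_release"]
    sd = noise.assay_sd["retinal_release"]
    for rep in range(1, n_replicates + 1):
        clean = A * np.exp(-truth.k_d_true * t) + truth.release_offset
        out.append(TimeCourse("retinal_release", "plain", rep, t,
                              clean + rng.normal(0, sd, t.size)))
    return out


def adapted_time_grids(truth: KineticTruth, n_points=(13, 61, 37)) -> dict:
    """Time grids scaled to resolve this pigment's rates.

    A fast pigment saturates the default grids; scale each window so the
    relevant exponential covers ~2.5 time constants, as an experimenter
    would when configuring the instrument for a fast cone pigment.
    """
    k_dark = (truth.v_dark_true + truth.background_rate) / truth.plateaus["gtpgs_dark"]
    k_fluor = (truth.v_light_true + truth.fluor_background_rate) / truth.plateaus["fluor_light"]
    return {
        "gtpgs_dark": np.linspace(0.0, 2.5 / k_dark, n_points[0]),
        "fluor_light": np.linspace(0.0, 2.5 / k_fluor, n_points[1]),
        "retinal_release": np.linspace(0.0, 2.5 / truth.k_d_true, n_points[2]),
    }


# ---------------------------------------------------------------------------
# Absorbance spectra with first-order pigment decay
# ---------------------------------------------------------------------------

#: Govardovskii et al. A1-pigment alpha-band template constants
_GOV_A, _GOV_B, _GOV_C, _GOV_D = 69.7, 28.0, -14.9, 0.674
_GOV_b, _GOV_c = 0.922, 1.104


def govardovskii_a1(wavelengths, lambda_max: float) -> np.ndarray:
    """Normalized A1 visual-pigment absorbance template (alpha + beta band)."""
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha_band = 1.0 / (
        np.exp(_GOV_A * (a - x))
        + np.exp(_GOV_B * (_GOV_b - x))
        + np.exp(_GOV_C * (_GOV_c - x))
        + _GOV_D
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta_band = 0.26 * np.exp(-(((wl - lam_beta) / b_beta) ** 2))
    return alpha_band + beta_band


DEFAULT_WAVELENGTHS = np.arange(300.0, 701.0, 1.0)


def gen_decay_spectra(
    lambda_max: float,
    decay_rate: float,
    timepoints,
    noise: NoiseModel,
    peak_absorbance: float = 0.1,
    wavelengths=None,
) -> list[tuple[float, Spectrum, Spectrum]]:
    """Absorbance time series of a pigment incubated at 37 degC.

    Pigment content declines as ``exp(-decay_rate * t)``.  For each
    timepoint a pre-bleach (dark) spectrum and a paired post-bleach
    spectrum are returned; bleaching with hydroxylamine under yellow
    light removes the pigment band, so their difference isolates the
    pigment that remained at time t.  Returns a list of
    ``(t, dark_spectrum, bleached_spectrum)``.
    """
    if not (350.0 <= lambda_max <= 650.0):
        raise InvalidLambdaMax(f"lambda_max {lambda_max} outside [350, 650] nm")
    if decay_rate < 0:
        raise InvalidRates("decay_rate must be >= 0")
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    rng = noise.rng(offset=1)
    template = peak_absorbance * govardovskii_a1(wl, lambda_max)
    out = []
    for t in timepoints:
        scale = np.exp(-decay_rate * float(t))
        drift = noise.drift_amplitude * np.sin(wl / 200.0 + float(t))
        dark = scale * template + drift + rng.normal(0, noise.spectral_sd, wl.size)
        bleached = drift + rng.normal(0, noise.spectral_sd, wl.size)
        out.append(
            (
                float(t),
                Spectrum(wl, dark, label=f"t={t:g}s dark"),
                Spectrum(wl, bleached, label=f"t={t:g}s bleached"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Sequence evolution on a tree
# ---------------------------------------------------------------------------

def gen_alignment(
    tree: Topology,
    model: EvolModel,
    n_sites: int,
    seed: int = 0,
) -> Alignment:
    """Evolve i.i.d. amino-acid sites along ``tree``.

    Each site draws a gamma-category rate, a root state from the
    stationary frequencies, and child states through ``exp(Q t r)`` along
    every branch.
    """
    rng = np.random.default_rng(seed % 2**31)
    sub = model.model
    rates = model.rates
    n_tips = tree.n_tips

    cats = rng.integers(0, rates.k, size=n_sites)
    order = tree.postorder()
    root = order[-1][0]
    preorder = order[::-1]  # parents before children

    states = {root: rng.choice(20, size=n_sites, p=sub.frequencies)}
    for node, parent, blen in preorder:
        if parent == -1:
            continue
        parent_states = states[parent]
        child_states = np.empty(n_sites, dtype=np.int64)
        for c in range(rates.k):
            mask = cats == c
            if not mask.any():
                continue
            P = sub.transition_matrix(blen * rates.rates[c])
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0
            u = rng.random(int(mask.sum()))
            rows = cum[parent_states[mask]]
            child_states[mask] = (u[:, None] > rows).sum(axis=1)
        states[node] = child_states

    sites = np.vstack([states[i].astype(np.int8) for i in range(n_tips)])
    return Alignment(tree.tips, sites)


# ---------------------------------------------------------------------------
# Exchangeable null site-likelihood matrices
# ---------------------------------------------------------------------------

def gen_null_sitelikes(
    n_sites: int,
    n_topologies: int,
    seed: int = 0,
    site_sd: float = 0.5,
    noise_sd: float = 0.1,
    base: float = -3.0,
) -> SiteLikelihoodMatrix:
    """Exchangeable-column null matrix for test calibration.

    Each site has a shared level (the realized log-likelihood of that
    column, identical in expectation across topologies) plus i.i.d.
    Gaussian topology-specific contributions — the least-favourable null
    in which no topology is truly better than any other.
    """
    if n_topologies < 2:
        raise EmptyMatrix(f"need >= 2 topologies, got {n_topologies}")
    rng = np.random.default_rng(seed % 2**31)
    mu = base + site_sd * rng.standard_normal(n_sites)
    eps = noise_sd * rng.standard_normal((n_sites, n_topologies))
    L = np.minimum(mu[:, None] + eps, -1e-12)
    return SiteLikelihoodMatrix(L, tuple(range(n_topologies)), "null")
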
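"""Topology tests on a per-site log-likelihood matrix.

All tests are RELL-based (resampling estimated log-likelihoods): bootstrap
replicates resample site indices and sum the stored per-site lnL values,
with no re-optimization — the standard CONSEL-style practice.

* KH: centered replicate distribution of the lnL difference between two
  pre-specified topologies; two-sided by default.
* SH: each topology centered at its own replicate mean; the null statistic
  is the max over topologies of the centered lnL minus the topology's own,
  which corrects for selecting the ML topology and is conservative.
* AU: multiscale bootstrap.  Bootstrap proportions BP(r) at several
  resample-size scales r are fitted by the signed-distance/curvature model
  z(r) = Phi^-1(1 - BP(r)) = d sqrt(r) + c / sqrt(r), by maximum
  likelihood on the binomial counts (weighted least squares as the
  starting point and fallback); p_AU = 1 - Phi(d - c).

Ties for "best topology in a replicate" are split uniformly at random
(seeded), so BP sums to 1 over topologies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .errors import EmptyMatrix
from .phylo import SiteLikelihoodMatrix

#: default multiscale-bootstrap scales
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))
DEFAULT_B = 10_000
SIGNIFICANCE = 0.05


# ---------------------------------------------------------------------------
# RELL resampling
# ---------------------------------------------------------------------------

def rell_resample(
    L: SiteLikelihoodMatrix | np.ndarray,
    B: int,
    scale: float = 1.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """B replicate total-lnL rows by resampling sites with replacement.

    At scale ``r`` each replicate sums ``round(r * n_sites)`` site draws.
    Returns an array of shape (B, n_topologies).
    """
    M = L.L if isinstance(L, SiteLikelihoodMatrix) else np.asarray(L, float)
    if M.ndim != 2 or M.size == 0:
        raise EmptyMatrix("site-likelihood matrix must be 2-D, non-empty")
    if B < 1 or scale <= 0:
        raise ValueError("need B >= 1 and scale > 0")
    n = M.shape[0]
    n_resample = max(int(round(scale * n)), 1)
    if rng is None:
        rng = np.random.default_rng(seed)
    # draw site indices with replacement; accumulate to per-replicate
    # count vectors via one flat bincount (fast path for large B)
    idx = rng.integers(0, n, size=(B, n_resample))
    flat = idx + np.arange(B)[:, None] * n
    W = np.bincount(flat.ravel(), minlength=B * n).reshape(B, n).astype(float)
    return W @ M


def _best_with_random_ties(totals: np.ndarray, rng: np.random.Generator):
    """Index of the best topology per replicate; exact ties broken
    uniformly at random."""
    mx = totals.max(axis=1, keepdims=True)
    ties = totals == mx
    picks = np.argmax(rng.random(totals.shape) * ties, axis=1)
    return picks


def bootstrap_proportions(
    L, B: int = DEFAULT_B, scale: float = 1.0, seed: int = 0, rng=None
) -> np.ndarray:
    """BP per topology: fraction of replicates in which it is best."""
    if rng is None:
        rng = np.random.default_rng(seed)
    totals = rell_resample(L, B, scale, rng=rng)
    best = _best_with_random_ties(totals, rng)
    T = totals.shape[1]
    return np.bincount(best, minlength=T) / B


# ---------------------------------------------------------------------------
# KH test
# ---------------------------------------------------------------------------

def kh_test(
    L,
    topo_i: int,
    topo_j: int,
    B: int = DEFAULT_B,
    seed: int = 0,
    alternative: str = "two-sided",
) -> float:
    """Kishino-Hasegawa test of topology i against topology j.

    The RELL replicate differences are centered at their own mean (the
    null of equal expected lnL); the p-value is the fraction of centered
    replicates at least as extreme as the observed difference.
    ``alternative="greater"`` gives the one-sided version (probability
    that i beats j by at least the observed margin).
    """
    if topo_i == topo_j:
        raise ValueError("KH needs two distinct topologies")
    M = L.L if isinstance(L, SiteLikelihoodMatrix) else np.asarray(L, float)
    delta_obs = float(M[:, topo_i].sum() - M[:, topo_j].sum())
    totals = rell_resample(M, B, 1.0, seed=seed)
    delta = totals[:, topo_i] - totals[:, topo_j]
    centered = delta - delta.mean()
    if alternative == "two-sided":
        return float(np.mean(np.abs(centered) >= abs(delta_obs)))
    elif alternative == "greater":
        return float(np.mean(centered >= delta_obs))
    raise ValueError(f"unknown alternative {alternative!r}")


# ---------------------------------------------------------------------------
# SH test
# ---------------------------------------------------------------------------

def sh_test(L, B: int = DEFAULT_B, seed: int = 0) -> np.ndarray:
    """Shimodaira-Hasegawa test: p-value per topology.

    Each topology's replicate lnL is centered at its own mean; the null
    statistic per replicate is ``max_k centered_k - centered_t`` and the
    observed statistic is the lnL deficit to the ML topology.
    """
    M = L.L if isinstance(L, SiteLikelihoodMatrix) else np.asarray(L, float)
    if M.shape[1] < 2:
        raise EmptyMatrix("SH needs >= 2 topologies")
    obs_totals = M.sum(axis=0)
    obs_delta = obs_totals.max() - obs_totals  # >= 0, 0 for ML topology
    totals = rell_resample(M, B, 1.0, seed=seed)
    centered = totals - totals.mean(axis=0, keepdims=True)
    null_stat = centered.max(axis=1, keepdims=True) - centered  # (B, T)
    return (null_stat >= obs_delta[None, :]).mean(axis=0)


# ---------------------------------------------------------------------------
# AU test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AuFit:
    """Per-topology AU result with multiscale-fit diagnostics."""

    p_au: float
    d: float  # signed distance
    c: float  # curvature
    rms_residual: float
    degenerate: bool  # BP was 0 or 1 at every scale
    fit_failed: bool


def _wls_fit(scales, bp, B):
    """Weighted least squares for z(r) = d sqrt(r) + c / sqrt(r)."""
    eps = 0.5 / B
    bp_c = np.clip(bp, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bp_c)
    # delta-method weight: var(z) = BP(1-BP) / (B phi(z)^2)
    w = B * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
    sq = np.sqrt(scales)
    X = np.column_stack([sq, 1.0 / sq])
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ z)
    resid = z - X @ beta
    return beta, float(np.sqrt(np.mean(resid**2)))


def _binomial_ml_fit(scales, counts, B, beta0):
    """Maximize the binomial likelihood of BP counts under the
    signed-distance/curvature model; beta0 from WLS."""
    sq = np.sqrt(scales)
    X = np.column_stack([sq, 1.0 / sq])

    def nll(beta):
        z = X @ beta
        p = np.clip(1.0 - norm.cdf(z), 1e-12, 1.0 - 1e-12)
        return -np.sum(counts * np.log(p) + (B - counts) * np.log(1.0 - p))

    res = minimize(nll, beta0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    return (res.x, True) if res.success else (beta0, False)


def au_test(
    L,
    scales=DEFAULT_SCALES,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> list[AuFit]:
    """Approximately unbiased test for every topology in the matrix.

    Needs scales both below and above 1.  Topologies whose BP is 0 (or 1)
    at every scale get p_AU 0 (or 1) with the degenerate flag set.
    """
    scales = np.asarray(scales, dtype=float)
    if scales.size < 2 or not (scales.min() < 1.0 <= scales.max()):
        raise ValueError("need >= 2 scales spanning values below and above 1")
    M = L.L if isinstance(L, SiteLikelihoodMatrix) else np.asarray(L, float)
    T = M.shape[1]
    rng = np.random.default_rng(seed)
    bp = np.vstack([
        bootstrap_proportions(M, B=B, scale=r, rng=rng) for r in scales
    ])  # (n_scales, T)

    out = []
    counts = np.round(bp * B)
    for t in range(T):
        bpt = bp[:, t]
        if (bpt == 0.0).all():
            out.append(AuFit(0.0, np.inf, 0.0, 0.0, True, False))
            continue
        if (bpt == 1.0).all():
            out.append(AuFit(1.0, -np.inf, 0.0, 0.0, True, False))
            continue
        beta0, rms = _wls_fit(scales, bpt, B)
        beta, ok = _binomial_ml_fit(scales, counts[:, t], B, beta0)
        d, c = float(beta[0]), float(beta[1])
        p = float(1.0 - norm.cdf(d - c))
        out.append(AuFit(p, d, c, rms, False, not ok))
    return out


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestConfig:
    B: int = DEFAULT_B
    scales: tuple = DEFAULT_SCALES
    significance: float = SIGNIFICANCE
    seed: int = 0
    kh_alternative: str = "two-sided"


def summarize_tests(
    L: SiteLikelihoodMatrix, config: TestConfig = TestConfig()
) -> pd.DataFrame:
    """One row per topology, ranked by total lnL.

    Columns: tree (1-based rank), topology_id, lnL, delta_lnL, BP, p_AU,
    p_KH (vs the ML topology), p_SH, not_rejected_au (p_AU >= the
    significance level), plus AU diagnostics.  Deterministic per seed.
    """
    M = L.L
    T = M.shape[1]
    totals = M.sum(axis=0)
    ml = int(np.argmax(totals))
    bp = bootstrap_proportions(M, B=config.B, scale=1.0, seed=config.seed)
    if T > 1:
        p_sh = sh_test(M, B=config.B, seed=config.seed + 1)
        au = au_test(M, scales=config.scales, B=config.B, seed=config.seed + 2)
        p_kh = np.array([
            1.0 if t == ml else kh_test(
                M, t, ml, B=config.B, seed=config.seed + 3,
                alternative=config.kh_alternative,
            )
            for t in range(T)
        ])
        p_au = np.array([a.p_au for a in au])
        d = np.array([a.d for a in au])
        c = np.array([a.c for a in au])
    else:
        p_sh = np.array([1.0])
        p_kh = np.array([1.0])
        p_au = np.array([1.0])
        d = np.array([0.0])
        c = np.array([0.0])

    df = pd.DataFrame(
        {
            "topology_id": list(L.topology_ids),
            "lnL": totals,
            "delta_lnL": totals.max() - totals,
            "BP": bp,
            "p_AU": p_au,
            "p_KH": p_kh,
            "p_SH": p_sh,
            "au_d": d,
            "au_c": c,
        }
    )
    df = df.sort_values("lnL", ascending=False).reset_index(drop=True)
    df.insert(0, "tree", np.arange(1, T + 1))
    df["not_rejected_au"] = df["p_AU"] >= config.significance
    return df
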
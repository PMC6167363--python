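"""Thermal isomerization rate of the retinal chromophore from assay traces.

Under a two-step scheme (inactive pigment R -> active R* at rate k_th,
R* decaying at rate k_d), the dark steady state gives

    k_th = (v_dark / v_light) * k_d

where v_dark is the initial rate of G-protein activation in darkness,
v_light the initial rate per flash-activated pigment, and k_d the decay
rate of the active state.  Each trace is fitted by a single exponential;
the initial rate is the t -> 0 derivative of the fit, A*k.  Means and
SEMs are taken over replicates and combined with first-order error
propagation:

    M_th = (M_dark / M_light) * M_d
    e_th = M_th * sqrt((e_dark/M_dark)^2 + (e_light/M_light)^2 + (e_d/M_d)^2)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import ttest_ind

from .errors import (
    AssayMismatch,
    DegenerateSignal,
    FitDidNotConverge,
    MissingReference,
    NonpositiveDenominator,
)
from .io import TimeCourse


# ---------------------------------------------------------------------------
# Single-exponential fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpFit:
    """A(1-e^(-kt))+c (rise) or A e^(-kt)+c (decay) least-squares fit."""

    amplitude: float
    rate: float
    offset: float
    covariance: np.ndarray  # 3x3 for (A, k, c)
    direction: str

    @property
    def initial_rate(self) -> float:
        """|d signal/dt| at t = 0 of the fitted exponential: A*k."""
        return self.amplitude * self.rate

    @property
    def initial_rate_se(self) -> float:
        """Delta-method standard error of A*k from the fit covariance."""
        g = np.array([self.rate, self.amplitude, 0.0])
        var = float(g @ self.covariance @ g)
        return float(np.sqrt(max(var, 0.0)))


def fit_single_exponential(tc: TimeCourse, direction: str) -> ExpFit:
    """Nonlinear least-squares single-exponential fit of one trace.

    Initial guesses come from the signal range and a log-linearized
    slope.  A trace whose signal range is below 10 machine epsilons of
    its absolute mean is unidentifiable in (A, k) and raises
    :class:`DegenerateSignal` rather than reporting a zero rate.
    """
    if direction not in ("rise", "decay"):
        raise ValueError(f"direction must be 'rise' or 'decay', got {direction!r}")
    t = tc.times - tc.times[0]
    y = tc.signal
    rng_y = float(y.max() - y.min())
    if rng_y < 10 * np.finfo(float).eps * max(1.0, abs(float(y.mean()))):
        raise DegenerateSignal(
            f"signal range {rng_y:g} too small in "
            f"({tc.assay}, {tc.condition}, rep {tc.replicate})"
        )

    span = t[-1] - t[0]
    min_step = float(np.diff(t).min())
    # profile likelihood over k: for fixed k the model is linear in (A, c),
    # so a 1-D bounded search over log k is exact, fast and immune to the
    # (A, k) ridge of nearly-linear traces
    k_lo, k_hi = 1e-4 / span, 10.0 / min_step

    def basis(k):
        return 1.0 - np.exp(-k * t) if direction == "rise" else np.exp(-k * t)

    def profiled(k):
        X = np.column_stack([basis(k), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return float(resid @ resid), coef

    res = minimize_scalar(
        lambda lk: profiled(np.exp(lk))[0],
        bounds=(np.log(k_lo), np.log(k_hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    k = float(np.exp(res.x))
    rss, (A, c) = profiled(k)
    if not (np.isfinite(A) and np.isfinite(k) and np.isfinite(c)):
        raise FitDidNotConverge(
            f"non-finite fit in ({tc.assay}, {tc.condition}, rep {tc.replicate})"
        )

    # covariance of (A, k, c) from the full Jacobian at the optimum
    ekt = np.exp(-k * t)
    dA = basis(k)
    dk = A * t * ekt if direction == "rise" else -A * t * ekt
    J = np.column_stack([dA, dk, np.ones_like(t)])
    dof = max(t.size - 3, 1)
    sigma2 = rss / dof
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pcov = sigma2 * np.linalg.pinv(J.T @ J)
    return ExpFit(float(A), k, float(c), pcov, direction)


# ---------------------------------------------------------------------------
# Replicate-level rate estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateEstimate:
    """Mean +/- SEM of one measured quantity over replicates."""

    quantity: str  # v_dark | v_light | k_d
    mean: float
    sem: float
    n: int
    values: tuple[float, ...] = ()
    flags: tuple[str, ...] = ()


def _mean_sem(values: list[float], quantity: str, flags=()) -> RateEstimate:
    arr = np.asarray(values, dtype=float)
    n = arr.size
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    fl = list(flags)
    if n == 1:
        fl.append("single_replicate")
    return RateEstimate(quantity, float(arr.mean()), sem, n, tuple(arr), tuple(fl))


def _pair_by_replicate(a: list[TimeCourse], b: list[TimeCourse]):
    da = {tc.replicate: tc for tc in a}
    db = {tc.replicate: tc for tc in b}
    common = sorted(set(da) & set(db))
    if not common:
        raise AssayMismatch("no common replicate ids between the two samples")
    return [(da[r], db[r]) for r in common]


def estimate_v_dark(
    traces_n: list[TimeCourse], traces_7mr: list[TimeCourse]
) -> RateEstimate:
    """Initial dark activation rate: per-replicate difference of the
    native-retinal sample's initial rate and the locked-retinal (7mr)
    background control's, averaged over replicates.

    Negative differences are reported and flagged, never clipped.
    """
    for tc in traces_n + traces_7mr:
        if tc.assay != "gtpgs_dark":
            raise AssayMismatch(f"expected gtpgs_dark traces, got {tc.assay}")
    if not traces_n or not traces_7mr:
        raise AssayMismatch("both sample and control trace lists are required")
    values = []
    for tc_n, tc_b in _pair_by_replicate(traces_n, traces_7mr):
        v_n = fit_single_exponential(tc_n, "rise").initial_rate
        try:
            v_b = fit_single_exponential(tc_b, "rise").initial_rate
        except DegenerateSignal:
            v_b = 0.0  # flat control trace carries no background rate
        values.append(v_n - v_b)
    flags = ("negative_rate",) if np.mean(values) < 0 else ()
    return _mean_sem(values, "v_dark", flags)


def estimate_v_light(
    with_gt: list[TimeCourse], without_gt: list[TimeCourse]
) -> RateEstimate:
    """Initial light-activated rate: per-replicate difference of the
    fluorescence rise with and without G protein."""
    for tc in with_gt + without_gt:
        if tc.assay != "fluor_light":
            raise AssayMismatch(f"expected fluor_light traces, got {tc.assay}")
    if not with_gt or not without_gt:
        raise AssayMismatch("both with-Gt and without-Gt trace lists are required")
    values = []
    for tc_w, tc_o in _pair_by_replicate(with_gt, without_gt):
        v_w = fit_single_exponential(tc_w, "rise").initial_rate
        try:
            v_o = fit_single_exponential(tc_o, "rise").initial_rate
        except DegenerateSignal:
            v_o = 0.0
        values.append(v_w - v_o)
    flags = ("negative_rate",) if np.mean(values) < 0 else ()
    return _mean_sem(values, "v_light", flags)


def estimate_k_d(traces: list[TimeCourse]) -> RateEstimate:
    """Active-state decay rate from the retinal-release fluorescence
    decay, one fitted rate per replicate."""
    if not traces:
        raise AssayMismatch("no retinal_release traces")
    values = []
    for tc in sorted(traces, key=lambda tc: tc.replicate):
        if tc.assay != "retinal_release":
            raise AssayMismatch(f"expected retinal_release traces, got {tc.assay}")
        try:
            values.append(fit_single_exponential(tc, "decay").rate)
        except FitDidNotConverge as exc:
            raise FitDidNotConverge(f"replicate {tc.replicate}: {exc}") from exc
    return _mean_sem(values, "k_d")


# ---------------------------------------------------------------------------
# k_th with error propagation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KthResult:
    """Thermal isomerization rate with propagated SEM."""

    mean: float  # M_th, s^-1
    sem: float  # e_th, s^-1
    v_dark: RateEstimate
    v_light: RateEstimate
    k_d: RateEstimate
    flags: tuple[str, ...] = ()
    replicate_values: tuple[float, ...] = ()


def compute_k_th(
    v_dark: RateEstimate, v_light: RateEstimate, k_d: RateEstimate
) -> KthResult:
    """M_th = (M_dark/M_light) M_d with first-order error propagation.

    A non-positive v_dark mean yields a flagged non-positive M_th (no
    silent clipping); a non-positive v_light or k_d mean is an error
    because the ratio is then undefined.
    """
    if v_light.mean <= 0 or k_d.mean <= 0:
        raise NonpositiveDenominator(
            f"M_light = {v_light.mean:g}, M_d = {k_d.mean:g}"
        )
    m_th = (v_dark.mean / v_light.mean) * k_d.mean
    rel = 0.0
    if v_dark.mean != 0:
        rel += (v_dark.sem / v_dark.mean) ** 2
    rel += (v_light.sem / v_light.mean) ** 2 + (k_d.sem / k_d.mean) ** 2
    e_th = abs(m_th) * np.sqrt(rel)
    flags = []
    if v_dark.mean <= 0:
        flags.append("nonpositive_v_dark")

    # replicate-level k_th values (paired by replicate index) for t tests
    n = min(len(v_dark.values), len(v_light.values), len(k_d.values))
    reps = tuple(
        (v_dark.values[i] / v_light.values[i]) * k_d.values[i]
        for i in range(n)
        if v_light.values[i] > 0 and k_d.values[i] > 0
    )
    return KthResult(float(m_th), float(e_th), v_dark, v_light, k_d,
                     tuple(flags), reps)


def estimate_k_th_from_bundle(traces: list[TimeCourse]) -> KthResult:
    """Convenience: route a full assay bundle through the three
    estimators and combine."""
    by = lambda assay, cond: [
        tc for tc in traces if tc.assay == assay and tc.condition == cond
    ]
    v_dark = estimate_v_dark(by("gtpgs_dark", "pigment_n"),
                             by("gtpgs_dark", "pigment_7mr"))
    v_light = estimate_v_light(by("fluor_light", "with_Gt"),
                               by("fluor_light", "without_Gt"))
    k_d = estimate_k_d(by("retinal_release", "plain"))
    return compute_k_th(v_dark, v_light, k_d)


# ---------------------------------------------------------------------------
# Cross-pigment comparison
# ---------------------------------------------------------------------------

def compare_relative_rates(
    results: dict[str, KthResult], reference: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Rate constants relative to a reference pigment with a two-tailed
    pooled-variance (Student) t test on replicate-level k_th values.

    Returns a DataFrame with columns pigment, relative_k_th, p_value,
    significant (p < ``alpha``).
    """
    if reference not in results:
        raise MissingReference(f"reference pigment {reference!r} absent")
    ref = results[reference]
    rows = []
    for name, res in results.items():
        if name == reference:
            rel, p = 1.0, 1.0
        else:
            rel = res.mean / ref.mean
            a = np.asarray(res.replicate_values, float)
            b = np.asarray(ref.replicate_values, float)
            if a.size > 1 and b.size > 1:
                if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
                    p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
                else:
                    p = float(ttest_ind(a, b, equal_var=True).pvalue)
            else:
                p = float("nan")
        rows.append(
            {
                "pigment": name,
                "relative_k_th": rel,
                "p_value": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)


def kth_results_table(results: dict[str, KthResult]) -> pd.DataFrame:
    """Summary table mirroring a per-pigment rate panel."""
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "pigment": name,
                "M_dark": r.v_dark.mean, "e_dark": r.v_dark.sem,
                "M_light": r.v_light.mean, "e_light": r.v_light.sem,
                "M_d": r.k_d.mean, "e_d": r.k_d.sem,
                "M_th": r.mean, "e_th": r.sem,
                "n": r.v_dark.n,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
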
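"""Two-exponential influx/efflux tracer kinetics.

A voxel or cluster time course of percent signal change after intracisternal
contrast injection is modelled as

    f(t) = c1 * (1 - exp(-t / tau_in)) + c2 * (exp(-t / tau_out) - 1)

with gains c1, c2 >= 0 (percent units), influx time constant tau_in and efflux
time constant tau_out (minutes, t = 0 at the start of infusion). f(0) = 0
identically and f -> c1 - c2 as t -> infinity. The influx term captures tracer
arrival; the efflux term its clearance. Fits are nonlinear least squares with
a deterministic multi-start grid; group differences in the fitted time
constants and in model-free AUC are assessed with two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares, nnls

__all__ = [
    "KineticParams",
    "FitConfig",
    "FitResult",
    "GroupComparison",
    "model_eval",
    "model_auc",
    "time_to_peak",
    "fit_double_exponential",
    "auc",
    "compare_groups",
    "cluster_kinetics_table",
    "roi_auc_analysis",
]


@dataclass(frozen=True)
class KineticParams:
    """Gains (percent) and time constants (minutes) of the influx/efflux model."""

    c1: float
    c2: float
    tau_in: float
    tau_out: float

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("gains must be non-negative")
        for name in ("tau_in", "tau_out"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.tau_in, self.tau_out])


def model_eval(params: KineticParams, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate f(t); exact at t = 0 where both exponential terms vanish."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("model is defined for t >= 0 (minutes post-injection)")
    out = params.c1 * (1.0 - np.exp(-t / params.tau_in)) + params.c2 * (
        np.exp(-t / params.tau_out) - 1.0
    )
    return float(out) if out.ndim == 0 else out


def model_auc(params: KineticParams, t_start: float, t_end: float) -> float:
    """Closed-form integral of f over [t_start, t_end] (percent * minutes)."""

    def antiderivative(t: float) -> float:
        return params.c1 * (t + params.tau_in * np.exp(-t / params.tau_in)) + params.c2 * (
            -params.tau_out * np.exp(-t / params.tau_out) - t
        )

    return antiderivative(t_end) - antiderivative(t_start)


def time_to_peak(params: KineticParams) -> float | None:
    """Interior maximum of f, in minutes; None when f is monotone on [0, inf).

    f'(t) = c1/tau_in * exp(-t/tau_in) - c2/tau_out * exp(-t/tau_out); for
    distinct time constants the stationary point has the closed form
    t* = ln((c1 * tau_out) / (c2 * tau_in)) / (1/tau_in - 1/tau_out).
    An interior peak exists only when f is initially rising (c1/tau_in >
    c2/tau_out) and the influx is the faster process.
    """
    c1, c2, ti, to = params.c1, params.c2, params.tau_in, params.tau_out
    if c2 == 0 or c1 == 0:
        return None  # monotone saturation or pure washout
    rate_diff = 1.0 / ti - 1.0 / to
    if abs(rate_diff) < 1e-15:
        return None  # f' keeps one sign: monotone
    ratio = (c1 * to) / (c2 * ti)
    if ratio <= 0:
        return None
    t_star = np.log(ratio) / rate_diff
    if t_star <= 0 or not np.isfinite(t_star):
        return None
    # stationary point is a maximum only if f is rising before it
    slope0 = c1 / ti - c2 / to
    if slope0 <= 0:
        return None
    return float(t_star)


@dataclass
class FitConfig:
    """Deterministic multi-start settings for the nonlinear fit."""

    tau_in_starts: tuple[float, ...] = (1.0, 5.0, 15.0, 40.0)
    tau_out_starts: tuple[float, ...] = (30.0, 120.0)
    ftol: float = 1e-10
    xtol: float = 1e-12
    max_iterations: int = 1000
    random_fallback_starts: int = 16
    seed: int = 0
    tau_out_extrapolation_factor: float = 2.0  # flag tau_out > factor * window


@dataclass
class FitResult:
    """Outcome of fitting the kinetic model to one time course."""

    params: KineticParams
    sse: float
    converged: bool
    n_iterations: int
    starts_tried: int
    residuals: np.ndarray
    tau_out_extrapolated: bool = False


def _residuals_and_jac(t: np.ndarray, y: np.ndarray):
    """Residual and analytic Jacobian callables in (c1, c2, log ti, log to)."""

    def resid(p: np.ndarray) -> np.ndarray:
        c1, c2, lti, lto = p
        ti, to = np.exp(lti), np.exp(lto)
        return c1 * (1.0 - np.exp(-t / ti)) + c2 * (np.exp(-t / to) - 1.0) - y

    def jac(p: np.ndarray) -> np.ndarray:
        c1, c2, lti, lto = p
        ti, to = np.exp(lti), np.exp(lto)
        ein, eout = np.exp(-t / ti), np.exp(-t / to)
        J = np.empty((t.size, 4))
        J[:, 0] = 1.0 - ein
        J[:, 1] = eout - 1.0
        J[:, 2] = -c1 * t * ein / ti  # d/d log tau_in
        J[:, 3] = c2 * t * eout / to  # d/d log tau_out
        return J

    return resid, jac


def fit_double_exponential(
    times: Sequence[float],
    values: Sequence[float],
    config: FitConfig | None = None,
) -> FitResult:
    """Least-squares fit of the influx/efflux model to one time course.

    Positivity of the time constants is enforced by log-parameterization and
    of the gains by box bounds. Each start on the deterministic grid runs a
    trust-region-reflective solve; the best SSE wins. A seeded random-restart
    fallback triggers only if every grid start fails. Never raises on data:
    an unfittable trace yields ``converged=False`` with the best attempt.
    """
    cfg = config or FitConfig()
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 observations for a 4-parameter fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(t < 0):
        raise ValueError("times must be >= 0 minutes post-injection")

    resid, jac = _residuals_and_jac(t, y)
    span = float(y.max() - y.min())

    def _start(ti: float, to: float) -> np.ndarray:
        # variable projection: for fixed time constants the model is linear in
        # the gains, so each start opens with the exact non-negative solution
        A = np.column_stack([1.0 - np.exp(-t / ti), np.exp(-t / to) - 1.0])
        gains, _ = nnls(A, y)
        return np.array([max(gains[0], 1e-8), max(gains[1], 1e-8), np.log(ti), np.log(to)])

    starts = [_start(ti, to) for ti in cfg.tau_in_starts for to in cfg.tau_out_starts]
    # time constants confined to a generous physical range (0.01 min .. 10^4
    # min); below ~2 min the influx exponential is invisible at a 30-min first
    # sample, so an unbounded fit can crawl indefinitely along a flat valley
    lower = np.array([0.0, 0.0, np.log(1e-2), np.log(1e-2)])
    upper = np.array([np.inf, np.inf, np.log(1e4), np.log(1e4)])

    best = None
    n_tried = 0
    total_nfev = 0
    for x0 in starts:
        n_tried += 1
        try:
            res = least_squares(
                resid,
                x0,
                jac=jac,
                bounds=(lower, upper),
                method="trf",
                ftol=cfg.ftol,
                xtol=cfg.xtol,
                gtol=1e-12,
                max_nfev=cfg.max_iterations,
            )
        except Exception:  # pragma: no cover - optimizer internal failure
            continue
        total_nfev += res.nfev
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res)

    if best is None or not np.isfinite(best[0]):
        rng = np.random.default_rng(cfg.seed)
        for _ in range(cfg.random_fallback_starts):
            n_tried += 1
            x0 = np.array(
                [
                    max(abs(span), 1e-6) * rng.uniform(0.2, 2.0),
                    max(abs(span), 1e-6) * rng.uniform(0.2, 2.0),
                    np.log(rng.uniform(0.5, 60.0)),
                    np.log(rng.uniform(20.0, 200.0)),
                ]
            )
            try:
                res = least_squares(
                    resid, x0, jac=jac, bounds=(lower, upper), method="trf",
                    ftol=cfg.ftol, xtol=cfg.xtol, gtol=1e-12, max_nfev=cfg.max_iterations,
                )
            except Exception:  # pragma: no cover
                continue
            total_nfev += res.nfev
            sse = float(2.0 * res.cost)
            if best is None or sse < best[0]:
                best = (sse, res)
            if best[1].success:
                break

    if best is None:  # pragma: no cover - least_squares never raised in practice
        params = KineticParams(c1=0.0, c2=0.0, tau_in=1.0, tau_out=1.0)
        r = model_eval(params, t) - y
        return FitResult(params, float(r @ r), False, 0, n_tried, r)

    sse, res = best
    c1, c2, lti, lto = res.x
    params = KineticParams(
        c1=float(c1), c2=float(c2), tau_in=float(np.exp(lti)), tau_out=float(np.exp(lto))
    )
    window = float(t[-1] - t[0])
    return FitResult(
        params=params,
        sse=sse,
        converged=bool(res.success),
        n_iterations=total_nfev,
        starts_tried=n_tried,
        residuals=res.fun.copy(),
        tau_out_extrapolated=params.tau_out > cfg.tau_out_extrapolation_factor * window,
    )


def auc(times: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under the time course over the observed window."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points for an AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


@dataclass
class GroupComparison:
    """Two-sample comparison of one kinetic quantity across two groups."""

    statistic_name: str
    unit: str
    group_names: tuple[str, str]
    group_means: tuple[float, float]
    group_sems: tuple[float, float]
    n_per_group: tuple[int, int]
    t_statistic: float
    p_value: float
    significant: bool  # at alpha = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def compare_groups(
    per_subject_values: Mapping[str, Sequence[float]],
    statistic_name: str = "tau_in",
    unit: str = "min",
    welch: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided two-sample t-test between exactly two groups.

    Equal-variance (pooled) by default; Welch's correction by flag.
    """
    if len(per_subject_values) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    (name_a, vals_a), (name_b, vals_b) = per_subject_values.items()
    a = np.asarray(vals_a, dtype=float)
    b = np.asarray(vals_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
    sem_a = float(a.std(ddof=1) / np.sqrt(a.size))
    sem_b = float(b.std(ddof=1) / np.sqrt(b.size))
    p = float(p)
    if np.isnan(p):  # zero variance in both groups with equal means
        t_stat, p = 0.0, 1.0
    return GroupComparison(
        statistic_name=statistic_name,
        unit=unit,
        group_names=(name_a, name_b),
        group_means=(float(a.mean()), float(b.mean())),
        group_sems=(sem_a, sem_b),
        n_per_group=(a.size, b.size),
        t_statistic=float(t_stat),
        p_value=p,
        significant=p < alpha,
    )


def cluster_kinetics_table(
    fits: pd.DataFrame,
    group_a: str,
    group_b: str,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-cluster group comparison of fitted time constants.

    ``fits`` must hold columns (subject, group, cluster, tau_in, tau_out).
    Returns one row per cluster with mean +/- sem per group and the two
    t-test p-values, mirroring the usual influx/efflux reporting layout.
    """
    rows = []
    for cluster_id, sub in fits.groupby("cluster"):
        row: dict = {"cluster": cluster_id}
        for stat in ("tau_in", "tau_out"):
            vals = {
                group_a: sub.loc[sub["group"] == group_a, stat].to_numpy(),
                group_b: sub.loc[sub["group"] == group_b, stat].to_numpy(),
            }
            cmpres = compare_groups(vals, statistic_name=stat, welch=welch)
            row[f"{stat}_{group_a}_mean"] = cmpres.group_means[0]
            row[f"{stat}_{group_a}_sem"] = cmpres.group_sems[0]
            row[f"{stat}_{group_b}_mean"] = cmpres.group_means[1]
            row[f"{stat}_{group_b}_sem"] = cmpres.group_sems[1]
            row[f"{stat}_t"] = cmpres.t_statistic
            row[f"{stat}_p"] = cmpres.p_value
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)


def roi_auc_analysis(
    subject_matrices: Mapping[str, "object"],
    subject_groups: Mapping[str, str],
    roi_row_labels: np.ndarray,
    roi_names: Mapping[int, str],
    frame_times_min: np.ndarray,
    variance_threshold: float = 0.99,
    max_components: int | None = 3,
    welch: bool = False,
) -> tuple[pd.DataFrame, dict[str, GroupComparison]]:
    """Per-ROI AUC group comparison from subject-level PCA-denoised traces.

    For each subject: PCA-reconstruct the voxel time-course matrix, average
    within each ROI, integrate (trapezoid) over the observed window; then a
    two-sample t-test per ROI across the two groups. ``roi_row_labels`` gives
    the ROI label of each matrix row (0 = outside every ROI). Empty ROIs are
    skipped with a warning. Returns (per-subject AUC table, per-ROI
    comparisons).
    """
    import warnings as _warnings

    from .cluster import pca_reconstruct

    records = []
    for subject_id, matrix in subject_matrices.items():
        recon = pca_reconstruct(
            matrix, variance_threshold=variance_threshold, max_components=max_components
        ).reconstructed
        for label, name in roi_names.items():
            rows = roi_row_labels == label
            if not rows.any():
                _warnings.warn(f"ROI '{name}' (label {label}) is empty; skipped", stacklevel=2)
                continue
            trace = recon[rows].mean(axis=0)
            records.append(
                {
                    "subject": subject_id,
                    "group": subject_groups[subject_id],
                    "roi": name,
                    "auc": auc(frame_times_min, trace),
                }
            )
    table = pd.DataFrame(records)
    comparisons: dict[str, GroupComparison] = {}
    if not table.empty:
        groups = sorted(table["group"].unique())
        if len(groups) == 2:
            for roi_name, sub in table.groupby("roi"):
                vals = {g: sub.loc[sub["group"] == g, "auc"].to_numpy() for g in groups}
                comparisons[str(roi_name)] = compare_groups(
                    vals, statistic_name="AUC", unit="percent*min", welch=welch
                )
    return table, comparisons
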
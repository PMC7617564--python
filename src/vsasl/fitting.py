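"""Multi-start unconstrained least-squares estimation of voxel kinetics.

Four free parameters are estimated per voxel: perfusion ``f``, bolus duration,
apparent macrovascular blood volume ``macro_bv``, and macrovascular bolus
duration.  A quasi-Newton (BFGS) minimiser is run from a small grid of
starting values for the two durations; the converged solution with minimal
sum of squared residuals wins, with ties broken towards the smallest
durations so the flat-objective truncation regime resolves reproducibly.

The macrovascular bolus duration enters the model only through which readout
times fall inside the macrovascular bolus: the objective is piecewise constant
in it, so gradient steps never move it.  Its starting values therefore
enumerate every distinct step-edge basin -- the sampled readout times plus
zero -- and the winner is snapped down to the largest readout time it covers,
the smallest value in its equal-sse set.  Consequently the estimate is
interval-censored at the sampling resolution of the readout-time grid.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import minimize

from .model import (
    CBF_SCALE,
    AcquisitionTiming,
    PhysioConstants,
    TissueParams,
    readout_time,
)

__all__ = [
    "VoxelSeries",
    "FitResult",
    "MaskSpec",
    "RegionStats",
    "RegionSummary",
    "DEFAULT_BOLUS_STARTS",
    "DEFAULT_MACRO_BV_START",
    "objective",
    "fit_voxel",
    "postprocess_fit",
    "build_mask",
    "fit_image",
    "summarize_regions",
    "aggregate_subjects",
    "PARAM_KEYS",
]

# Bolus-duration starts span the physiological grey-matter range; the
# macrovascular-duration starts default to the data's step edges (see
# fit_voxel).
DEFAULT_BOLUS_STARTS: tuple[float, ...] = (0.5, 0.8, 1.2, 1.7, 2.3, 3.0)
DEFAULT_MACRO_BV_START: float = 1e-3

#: internal parameter scaling so BFGS sees O(1) coordinates
_SCALE = np.array([0.01, 1.0, 0.001, 1.0])

#: |f| below this (ml/g/s) leaves the bolus duration unconstrained by the data
_F_DEGENERATE = 1e-6

#: fitted bolus durations >= this fraction of max LCT are boundary-flagged
BOUNDARY_FRACTION = 0.98

PARAM_KEYS = ("f", "bolus_duration", "macro_bv", "macro_bolus_duration")
MAP_KEYS = PARAM_KEYS + (
    "cbf",
    "sse",
    "n_starts_converged",
    "boundary_flag",
    "bolus_unidentifiable",
    "macro_excluded",
    "converged",
)


@dataclass(frozen=True)
class VoxelSeries:
    """Difference-signal samples of one voxel across LCTs."""

    dm_values: np.ndarray
    lct_values: np.ndarray
    slice_index: int
    m0: float

    def __post_init__(self) -> None:
        dm = np.asarray(self.dm_values, dtype=float)
        lct = np.asarray(self.lct_values, dtype=float)
        if dm.shape != lct.shape or dm.ndim != 1:
            raise ValueError("dm_values and lct_values must be equal-length 1-D")
        if not self.m0 > 0:
            raise ValueError("m0 must be strictly positive")
        object.__setattr__(self, "dm_values", dm)
        object.__setattr__(self, "lct_values", lct)


@dataclass
class FitResult:
    """Winning parameter estimate of one voxel with fit diagnostics."""

    params: TissueParams
    sse: float
    n_starts_converged: int
    start_used: int
    converged: bool
    boundary_flag: bool = False
    bolus_unidentifiable: bool = False
    macro_excluded: bool = False
    start_sse: tuple[float, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class MaskSpec:
    """Thresholds for the grey-matter analysis mask and region definitions."""

    gm_pve_threshold: float = 0.50
    m0_fraction_threshold: float = 0.50
    region_pve_threshold: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "gm_pve_threshold",
            "m0_fraction_threshold",
            "region_pve_threshold",
        ):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class RegionStats:
    """Per-subject, per-region voxelwise medians."""

    region: str
    n_voxels: int
    medians: dict[str, float]


@dataclass
class RegionSummary:
    """Across-subject mean +/- SD of per-subject region medians."""

    region: str
    n_subjects: int
    per_subject_medians: dict[str, list[float]]
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    n_voxels: list[int] = field(default_factory=list)


def _model_and_jac(x: np.ndarray, t: np.ndarray, lct: np.ndarray, consts: PhysioConstants):
    """Normalised model (units of M0) and its Jacobian wrt (f, tau, mbv, tmac).

    The tmac column is identically zero: the step edge carries no usable
    gradient, which is exactly why tmac is explored by multi-start/profiling.
    """
    f, tau, mbv, tmac = x
    amp = 2.0 * consts.alpha * consts.alpha_bgs
    e_blood = np.exp(-t / consts.t1_blood)
    base = amp * e_blood
    n = t.size
    jac = np.zeros((n, 4))

    k = 1.0 / consts.t1_blood - 1.0 / consts.t1_tissue - f / consts.lambda_bt
    if tau > 0:
        te = np.minimum(tau, lct)
        xk = k * te
        small = np.abs(xk) < 1e-6
        xs = np.where(small, 1.0, xk)
        g = np.where(small, 1.0 - xk / 2.0 + xk * xk / 6.0, -np.expm1(-xs) / xs)
        smallp = np.abs(xk) < 1e-3
        xsp = np.where(smallp, 1.0, xk)
        gp = np.where(
            smallp,
            -0.5 + xk / 3.0 - xk * xk / 8.0,
            (np.exp(-xsp) * (xsp + 1.0) - 1.0) / (xsp * xsp),
        )
        ekt = np.exp(k * t)
        qp = ekt * g
        tissue = base * f * te * qp
        dqp_dk = ekt * (t * g + gp * te)
        jac[:, 0] = base * te * (qp - f * dqp_dk / consts.lambda_bt)
        on_tau = lct >= tau
        jac[:, 1] = np.where(on_tau, base * f * (qp + ekt * gp * k * te), 0.0)
    else:
        tissue = np.zeros(n)

    active = t <= tmac
    macro = np.where(active, base * mbv, 0.0)
    jac[:, 2] = np.where(active, base, 0.0)
    return tissue + macro, jac


def _sse_and_grad_numpy(z, y, t, lct, consts):
    x = z * _SCALE
    model, jac = _model_and_jac(x, t, lct, consts)
    r = model - y
    return float(r @ r), 2.0 * (jac.T @ r) * _SCALE


try:  # scalar-loop core; ~20x faster than the numpy path on short series
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _sse_grad_core(z, y, t, lct, amp, t1b_inv, k0, lam_inv, scale):  # pragma: no cover - jitted
        f = z[0] * scale[0]
        tau = z[1] * scale[1]
        mbv = z[2] * scale[2]
        tmac = z[3] * scale[3]
        k = k0 - f * lam_inv
        sse = 0.0
        gf = 0.0
        gtau = 0.0
        gmbv = 0.0
        for i in range(t.size):
            ti = t[i]
            base = amp * math.exp(-ti * t1b_inv)
            model = 0.0
            df = 0.0
            dtau = 0.0
            dmbv = 0.0
            if tau > 0.0:
                te = tau if tau < lct[i] else lct[i]
                xk = k * te
                if abs(xk) < 1e-6:
                    g = 1.0 - xk / 2.0 + xk * xk / 6.0
                else:
                    g = -math.expm1(-xk) / xk
                if abs(xk) < 1e-3:
                    gp = -0.5 + xk / 3.0 - xk * xk / 8.0
                else:
                    gp = (math.exp(-xk) * (xk + 1.0) - 1.0) / (xk * xk)
                ekt = math.exp(k * ti)
                qp = ekt * g
                model += base * f * te * qp
                df = base * te * (qp - f * ekt * (ti * g + gp * te) * lam_inv)
                if lct[i] >= tau:
                    dtau = base * f * (qp + ekt * gp * k * te)
            if ti <= tmac:
                model += base * mbv
                dmbv = base
            r = model - y[i]
            sse += r * r
            gf += r * df
            gtau += r * dtau
            gmbv += r * dmbv
        grad = np.empty(4)
        grad[0] = 2.0 * gf * scale[0]
        grad[1] = 2.0 * gtau * scale[1]
        grad[2] = 2.0 * gmbv * scale[2]
        grad[3] = 0.0
        return sse, grad

    def _sse_and_grad(z, y, t, lct, consts):
        return _sse_grad_core(
            z,
            y,
            t,
            lct,
            2.0 * consts.alpha * consts.alpha_bgs,
            1.0 / consts.t1_blood,
            1.0 / consts.t1_blood - 1.0 / consts.t1_tissue,
            1.0 / consts.lambda_bt,
            _SCALE,
        )

except ImportError:  # pragma: no cover - numba is normally present
    _sse_and_grad = _sse_and_grad_numpy


def objective(
    params: TissueParams,
    series: VoxelSeries,
    timing: AcquisitionTiming,
    consts: PhysioConstants,
) -> float:
    """Sum of squared residuals of the model against one voxel series."""
    t = readout_time(series.lct_values, series.slice_index, timing)
    x = np.array(
        [params.f, params.bolus_duration, params.macro_bv, params.macro_bolus_duration]
    )
    model, _ = _model_and_jac(x, t, np.asarray(series.lct_values, float), consts)
    r = model * params.m0 - series.dm_values
    return float(r @ r)


def _initial_f(y: np.ndarray, lct: np.ndarray, t: np.ndarray, consts) -> float:
    """Crude perfusion start from the two shortest-LCT points (qp ~ 1)."""
    amp = 2.0 * consts.alpha * consts.alpha_bgs
    with np.errstate(divide="ignore", invalid="ignore"):
        est = y[:2] / (amp * lct[:2] * np.exp(-t[:2] / consts.t1_blood))
    f0 = float(np.nanmean(est))
    if not math.isfinite(f0) or f0 <= 0:
        return 2e-3
    return min(max(f0, 1e-4), 0.1)


def fit_voxel(
    series: VoxelSeries,
    timing: AcquisitionTiming,
    consts: PhysioConstants,
    bolus_starts: tuple[float, ...] = DEFAULT_BOLUS_STARTS,
    macro_bolus_starts: tuple[float, ...] | None = None,
    macro_bv_start: float = DEFAULT_MACRO_BV_START,
    gtol: float = 1e-8,
    maxiter: int = 500,
) -> FitResult:
    """Multi-start quasi-Newton fit of one voxel.

    The start grid is the cartesian product of the bolus-duration starts and
    the macrovascular bolus-duration candidates.  By default the latter are
    the sampled readout times plus zero: the objective is piecewise constant
    in the macrovascular duration, so these edges enumerate every distinct
    basin the step edge can produce, whereas a fixed start grid silently
    mis-specifies the macrovascular active set.

    Requires at least 6 LCT samples (4 free parameters plus margin).  Fully
    deterministic: identical inputs and start grids give identical results.
    """
    lct = np.asarray(series.lct_values, dtype=float)
    if lct.size < 6:
        raise ValueError("need at least 6 LCT samples to fit 4 parameters")
    t = readout_time(lct, series.slice_index, timing)
    y = series.dm_values / series.m0
    max_lct = float(lct[-1])

    if macro_bolus_starts is None:
        macro_bolus_starts = (0.0, *t)
    f0 = _initial_f(y, lct, t, consts)
    args = (y, t, lct, consts)
    opts = {"gtol": gtol, "ftol": 1e-16, "maxiter": maxiter}

    solutions: list[tuple[float, np.ndarray, bool]] = []
    for tau0, tmac0 in product(bolus_starts, macro_bolus_starts):
        z0 = np.array([f0, tau0, macro_bv_start, tmac0]) / _SCALE
        try:
            res = minimize(
                _sse_and_grad, z0, args=args, jac=True, method="L-BFGS-B", options=opts
            )
            solutions.append((float(res.fun), res.x * _SCALE, bool(res.success)))
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            solutions.append((math.inf, np.full(4, np.nan), False))

    start_sse = tuple(s[0] for s in solutions)
    n_conv = sum(1 for s in solutions if s[2])
    finite = [i for i, s in enumerate(solutions) if math.isfinite(s[0])]
    if not finite:
        params = TissueParams(np.nan, np.nan, np.nan, np.nan, m0=series.m0)
        return FitResult(params, math.nan, 0, -1, False, start_sse=start_sse)

    # equal-sse ties resolve to the smallest durations, so the flat
    # truncation and step-edge regimes do not depend on start order
    sse_tol = 1e-7 * (float(y @ y) + 1e-12)
    best_sse = min(start_sse[i] for i in finite)
    ties = [i for i in finite if start_sse[i] <= best_sse + sse_tol]
    start_used = min(
        ties, key=lambda i: (solutions[i][1][3], max(solutions[i][1][1], 0.0))
    )
    sse, x, success = solutions[start_used]

    x = x.copy()
    # a non-positive bolus delivers nothing, leaving f unidentifiable: report
    # the minimal-norm representative of that equivalence class
    if x[1] <= 0:
        x[0] = 0.0
        x[1] = 0.0
    # flat-objective canonicalisation: any bolus >= max LCT is sse-equivalent
    if x[1] > max_lct:
        x[1] = max_lct
    # snap tmac down to the largest readout time it covers (smallest
    # equal-sse value); with no covered samples the macro term is absent
    covered = t[t <= x[3] + 1e-12]
    if covered.size:
        x[3] = float(covered[-1])
    else:
        x[3] = 0.0
        x[2] = 0.0

    params = TissueParams(
        f=float(x[0]),
        bolus_duration=float(x[1]),
        macro_bv=float(x[2]),
        macro_bolus_duration=float(x[3]),
        m0=series.m0,
    )
    return FitResult(
        params=params,
        sse=sse * series.m0**2,
        n_starts_converged=n_conv,
        start_used=start_used,
        converged=success,
        boundary_flag=x[1] >= BOUNDARY_FRACTION * max_lct,
        bolus_unidentifiable=abs(x[0]) < _F_DEGENERATE,
        start_sse=start_sse,
    )


def postprocess_fit(result: FitResult) -> FitResult:
    """Apply the physiological-consistency zeroing rules.

    Bolus duration is set to zero when perfusion is zero or negative, and the
    macrovascular bolus duration to zero when the macrovascular blood volume
    is zero or negative; such voxels are flagged for exclusion from
    macrovascular bolus-duration averages.
    """
    params = result.params
    out = dataclasses.replace(result)
    if not math.isfinite(params.f):
        return out
    bolus = params.bolus_duration
    tmac = params.macro_bolus_duration
    macro_excluded = result.macro_excluded
    if params.f <= 0:
        bolus = 0.0
    if params.macro_bv <= 0:
        tmac = 0.0
        macro_excluded = True
    out.params = dataclasses.replace(
        params, bolus_duration=bolus, macro_bolus_duration=tmac
    )
    out.macro_excluded = macro_excluded
    return out


def build_mask(gm_pve: np.ndarray, m0: np.ndarray, spec: MaskSpec | None = None) -> np.ndarray:
    """Grey-matter analysis mask.

    Voxels need a grey-matter partial volume estimate of at least the GM
    threshold and an M0 above the given fraction of the maximum M0 (rejecting
    signal drop-out areas).
    """
    spec = spec or MaskSpec()
    gm_pve = np.asarray(gm_pve)
    m0 = np.asarray(m0)
    if gm_pve.shape != m0.shape:
        raise ValueError(
            f"grid mismatch: gm_pve {gm_pve.shape} vs m0 {m0.shape}"
        )
    return (gm_pve >= spec.gm_pve_threshold) & (m0 > spec.m0_fraction_threshold * m0.max())


def fit_image(
    dm: np.ndarray,
    m0: np.ndarray,
    mask: np.ndarray,
    timing: AcquisitionTiming,
    consts: PhysioConstants,
    lct_keep: np.ndarray | None = None,
    **fit_kwargs,
) -> dict[str, np.ndarray]:
    """Voxelwise fit over a masked 4-D volume (x, y, z, LCT).

    Returns one 3-D map per parameter and diagnostic; unmasked voxels are NaN.
    ``lct_keep`` optionally selects a boolean subset of the LCT axis (used by
    the truncation analysis).  Per-voxel failures are recorded, not raised.
    """
    dm = np.asarray(dm, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dm.shape[:3] != mask.shape or m0.shape != mask.shape:
        raise ValueError("dm/m0/mask grids do not match")
    lct = np.asarray(timing.lct_values)
    if dm.shape[3] != lct.size:
        raise ValueError("dm LCT axis does not match timing.lct_values")
    if lct_keep is not None:
        lct_keep = np.asarray(lct_keep, dtype=bool)
        lct = lct[lct_keep]
        dm = dm[..., lct_keep]

    maps = {key: np.full(mask.shape, np.nan) for key in MAP_KEYS}
    for idx in zip(*np.nonzero(mask)):
        try:
            series = VoxelSeries(
                dm_values=dm[idx],
                lct_values=lct,
                slice_index=int(idx[2]),
                m0=float(m0[idx]),
            )
            r = postprocess_fit(fit_voxel(series, timing, consts, **fit_kwargs))
        except ValueError:
            warnings.warn(f"fit failed at voxel {idx}", RuntimeWarning, stacklevel=2)
            continue
        p = r.params
        maps["f"][idx] = p.f
        maps["cbf"][idx] = p.f * CBF_SCALE
        maps["bolus_duration"][idx] = p.bolus_duration
        maps["macro_bv"][idx] = p.macro_bv
        maps["macro_bolus_duration"][idx] = p.macro_bolus_duration
        maps["sse"][idx] = r.sse
        maps["n_starts_converged"][idx] = r.n_starts_converged
        maps["boundary_flag"][idx] = float(r.boundary_flag)
        maps["bolus_unidentifiable"][idx] = float(r.bolus_unidentifiable)
        maps["macro_excluded"][idx] = float(r.macro_excluded)
        maps["converged"][idx] = float(r.converged)
    return maps


_SUMMARY_PARAMS = ("cbf", "bolus_duration", "macro_bv", "macro_bolus_duration")


def summarize_regions(
    maps: dict[str, np.ndarray],
    atlas: np.ndarray,
    region_pve: dict[int, np.ndarray],
    region_names: dict[int, str],
    mask: np.ndarray,
    spec: MaskSpec | None = None,
) -> list[RegionStats]:
    """Per-region voxelwise medians for one subject.

    A region comprises masked voxels whose region partial volume estimate is
    at least the region threshold.  Macrovascular bolus-duration medians skip
    voxels flagged as having no characterisable macrovascular component.
    """
    spec = spec or MaskSpec()
    atlas = np.asarray(atlas)
    if atlas.shape != mask.shape:
        raise ValueError("atlas grid does not match mask grid")
    out: list[RegionStats] = []
    for label, name in region_names.items():
        pve = np.asarray(region_pve[label])
        sel = mask & (pve >= spec.region_pve_threshold)
        n_vox = int(sel.sum())
        medians: dict[str, float] = {}
        for key in _SUMMARY_PARAMS:
            vals = maps[key][sel]
            if key == "macro_bolus_duration":
                vals = vals[maps["macro_excluded"][sel] < 0.5]
            medians[key] = float(np.median(vals)) if vals.size else math.nan
        out.append(RegionStats(region=name, n_voxels=n_vox, medians=medians))
    return out


def aggregate_subjects(per_subject: list[list[RegionStats]]) -> list[RegionSummary]:
    """Across-subject mean +/- SD of per-subject region medians.

    Group statistics are computed over subjects, never pooled over voxels.
    """
    if not per_subject:
        return []
    n_sub = len(per_subject)
    summaries = []
    for i, first in enumerate(per_subject[0]):
        medians = {
            key: [subj[i].medians[key] for subj in per_subject]
            for key in _SUMMARY_PARAMS
        }
        mean = {}
        sd = {}
        for key, vals in medians.items():
            arr = np.asarray(vals, dtype=float)
            good = arr[np.isfinite(arr)]
            mean[key] = float(good.mean()) if good.size else math.nan
            sd[key] = float(good.std(ddof=1)) if good.size > 1 else math.nan
        summaries.append(
            RegionSummary(
                region=first.region,
                n_subjects=n_sub,
                per_subject_medians=medians,
                group_mean=mean,
                group_sd=sd,
                n_voxels=[subj[i].n_voxels for subj in per_subject],
            )
        )
    return summaries
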
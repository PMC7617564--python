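"""Cerebrovascular reactivity computations.

Per-LCT percentage change of the difference signal between normocapnia and
hypercapnia, model-based CVR in %/mmHg from fitted CBF, and the LCT-truncation
refit that demonstrates how capping the sampled LCT range censors long bolus
durations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .fitting import MaskSpec, build_mask, fit_image
from .model import PhysioConstants
from .synthetic import Cohort, StudyImage

__all__ = [
    "CvrResult",
    "TruncationResult",
    "dm_percent_change",
    "cohort_dm_percent_change",
    "cvr_from_cbf",
    "group_cvr",
    "truncation_experiment",
]


@dataclass
class CvrResult:
    """Group CVR summary: per-subject values are first-class citizens.

    The group statistic is the mean +/- SD of per-subject CVR values, not the
    CVR of group-mean CBF -- the order matters.
    """

    per_subject: np.ndarray
    mean: float
    sd: float
    delta_petco2: np.ndarray


@dataclass
class TruncationResult:
    """Paired full-range vs truncated-range grey-matter fit summaries."""

    max_lct: float
    full_gm_median: dict[str, float]
    truncated_gm_median: dict[str, float]
    full_boundary_fraction: float
    truncated_boundary_fraction: float
    full_maps: dict[str, np.ndarray]
    truncated_maps: dict[str, np.ndarray]


def dm_percent_change(
    dm_normo: np.ndarray,
    dm_hyper: np.ndarray,
    region_masks: dict[str, np.ndarray],
) -> np.ndarray:
    """Per-LCT median percentage signal increase, averaged across regions.

    Voxelwise change is ``100 (hyper - normo) / normo``; voxels with a
    non-positive normocapnic signal at a given LCT are excluded from that
    LCT's median.  The median is taken within each region, then averaged
    across regions.
    """
    dm_normo = np.asarray(dm_normo, dtype=float)
    dm_hyper = np.asarray(dm_hyper, dtype=float)
    if dm_normo.shape != dm_hyper.shape:
        raise ValueError("condition stacks must share LCT lists and grids")
    n_lct = dm_normo.shape[-1]
    per_region = np.full((len(region_masks), n_lct), np.nan)
    for r, (name, sel) in enumerate(region_masks.items()):
        base = dm_normo[sel]  # (n_vox, n_lct)
        high = dm_hyper[sel]
        for i in range(n_lct):
            ok = base[:, i] > 0
            n_excl = int((~ok).sum())
            if not ok.any():
                warnings.warn(
                    f"region {name}: all voxels excluded at LCT index {i}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            if n_excl:
                warnings.warn(
                    f"region {name}: {n_excl} non-positive baseline voxels "
                    f"excluded at LCT index {i}",
                    RuntimeWarning,
                    stacklevel=2,
                )
            pct = 100.0 * (high[ok, i] - base[ok, i]) / base[ok, i]
            per_region[r, i] = np.median(pct)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(per_region, axis=0)


def _region_masks(image: StudyImage, spec: MaskSpec) -> dict[str, np.ndarray]:
    mask = build_mask(image.gm_pve, image.m0, spec)
    return {
        image.region_names[label]: mask & (pve >= spec.region_pve_threshold)
        for label, pve in image.region_pve.items()
    }


def cohort_dm_percent_change(
    cohort: Cohort,
    normo: str = "normocapnia",
    hyper: str = "hypercapnia",
    mask_spec: MaskSpec | None = None,
) -> np.ndarray:
    """Region- and subject-averaged per-LCT percent signal change."""
    mask_spec = mask_spec or MaskSpec()
    curves = []
    for subj in cohort.subjects:
        img_n = subj.images[normo]
        img_h = subj.images[hyper]
        masks = _region_masks(img_n, mask_spec)
        curves.append(dm_percent_change(img_n.dm, img_h.dm, masks))
    return np.nanmean(np.vstack(curves), axis=0)


def cvr_from_cbf(cbf_normo: float, cbf_hyper: float, delta_petco2: float) -> float:
    """CVR in %/mmHg: 100 (CBF_hyper - CBF_normo) / CBF_normo / dPETCO2.

    Returns NaN for a non-positive baseline; a non-positive PETCO2 increase is
    a caller error.
    """
    if not delta_petco2 > 0:
        raise ValueError("delta_petco2 must be strictly positive")
    if not cbf_normo > 0:
        return math.nan
    return 100.0 * (cbf_hyper - cbf_normo) / cbf_normo / delta_petco2


def group_cvr(cbf_normo, cbf_hyper, delta_petco2) -> CvrResult:
    """Per-subject CVR, then mean +/- SD across subjects."""
    cbf_normo = np.asarray(cbf_normo, dtype=float)
    cbf_hyper = np.asarray(cbf_hyper, dtype=float)
    delta_petco2 = np.asarray(delta_petco2, dtype=float)
    if not cbf_normo.shape == cbf_hyper.shape == delta_petco2.shape:
        raise ValueError("per-subject arrays must have matching lengths")
    vals = np.array(
        [
            cvr_from_cbf(n, h, d)
            for n, h, d in zip(cbf_normo, cbf_hyper, delta_petco2)
        ]
    )
    good = vals[np.isfinite(vals)]
    return CvrResult(
        per_subject=vals,
        mean=float(good.mean()) if good.size else math.nan,
        sd=float(good.std(ddof=1)) if good.size > 1 else math.nan,
        delta_petco2=delta_petco2,
    )


def truncation_experiment(
    study: StudyImage,
    max_lct: float,
    consts: PhysioConstants | None = None,
    mask_spec: MaskSpec | None = None,
    **fit_kwargs,
) -> TruncationResult:
    """Refit one subject using only LCTs <= ``max_lct``.

    Returns paired grey-matter medians and the fraction of masked voxels
    whose bolus-duration estimate sits at the sampled-range boundary.
    At least 6 LCT samples must survive the cut.
    """
    consts = consts or PhysioConstants()
    mask_spec = mask_spec or MaskSpec()
    lct = np.asarray(study.timing.lct_values)
    keep = lct <= max_lct + 1e-12
    if keep.sum() < 6:
        raise ValueError("fewer than 6 LCT samples remain after truncation")
    mask = build_mask(study.gm_pve, study.m0, mask_spec)

    full_maps = fit_image(study.dm, study.m0, mask, study.timing, consts, **fit_kwargs)
    trunc_maps = fit_image(
        study.dm, study.m0, mask, study.timing, consts, lct_keep=keep, **fit_kwargs
    )

    def gm_median(maps):
        return {
            key: float(np.nanmedian(maps[key][mask]))
            for key in ("cbf", "bolus_duration", "macro_bv", "macro_bolus_duration")
        }

    def boundary_fraction(maps):
        flags = maps["boundary_flag"][mask]
        flags = flags[np.isfinite(flags)]
        return float(flags.mean()) if flags.size else math.nan

    return TruncationResult(
        max_lct=float(max_lct),
        full_gm_median=gm_median(full_maps),
        truncated_gm_median=gm_median(trunc_maps),
        full_boundary_fraction=boundary_fraction(full_maps),
        truncated_boundary_fraction=boundary_fraction(trunc_maps),
        full_maps=full_maps,
        truncated_maps=trunc_maps,
    )
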
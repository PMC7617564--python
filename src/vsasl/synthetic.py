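"""Synthetic multi-subject phantom studies for the VSASL kinetic pipeline.

Generates everything the downstream stages consume -- difference-signal
stacks per LCT, M0, grey-matter partial volume, an integer region atlas with
per-region partial volume maps, and ground-truth parameter maps -- so the
full analysis is testable without acquired data.

Across-subject variability is modelled region-wise: one parameter draw per
region per subject from normal distributions (negative draws are redrawn),
matching the way group summaries report across-participant spreads of region
medians.  Noise is additive Gaussian on the difference signal: each of the
averaged tag/control pairs contributes noise with standard deviation
``noise_sd * M0 * sqrt(2)`` (the subtraction of two noisy images).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    CBF_SCALE,
    AcquisitionTiming,
    PhysioConstants,
    macro_signal,
    tissue_signal,
)

__all__ = [
    "ParamDist",
    "RegionSpec",
    "Condition",
    "PhantomSpec",
    "Phantom",
    "StudyImage",
    "SubjectData",
    "Cohort",
    "make_phantom",
    "simulate_study",
    "simulate_cohort",
    "experiment1_preset",
    "experiment2_preset",
    "EXPERIMENT1_LCTS",
    "EXPERIMENT2_LCTS",
    "REGION_TABLE",
    "gm_row",
]

EXPERIMENT1_LCTS = (0.55, 0.66, 0.8, 0.96, 1.15, 1.39, 1.67, 2.0, 2.4, 2.9, 3.5)
EXPERIMENT2_LCTS = (0.55, 0.66, 0.8, 0.96, 1.15, 1.39, 1.67, 2.0)

# Group parameter estimates (mean, SD across participants): bolus duration [s]
# and CBF [ml/100 g/min] per region, for the three resting cut-off velocities
# and the normocapnia ("air") / hypercapnia ("co2") conditions.
REGION_TABLE: dict[str, dict[str, tuple[tuple[float, float], tuple[float, float]]]] = {
    "caudate": {
        "2cm/s": ((1.58, 0.24), (35, 9)),
        "3cm/s": ((1.60, 0.34), (36, 8)),
        "4cm/s": ((1.77, 0.51), (32, 6)),
        "air": ((1.41, 0.31), (36, 9)),
        "co2": ((1.15, 0.30), (47, 14)),
    },
    "cerebellum": {
        "2cm/s": ((2.41, 0.46), (53, 9)),
        "3cm/s": ((2.33, 0.51), (50, 9)),
        "4cm/s": ((2.16, 0.51), (47, 10)),
        "air": ((1.86, 0.17), (50, 10)),
        "co2": ((1.54, 0.26), (77, 17)),
    },
    "frontal_lobe": {
        "2cm/s": ((2.02, 0.26), (52, 8)),
        "3cm/s": ((1.94, 0.30), (52, 8)),
        "4cm/s": ((1.90, 0.38), (52, 10)),
        "air": ((1.56, 0.24), (56, 13)),
        "co2": ((1.31, 0.25), (82, 22)),
    },
    "insula": {
        "2cm/s": ((1.88, 0.49), (43, 4)),
        "3cm/s": ((1.89, 0.59), (42, 6)),
        "4cm/s": ((1.95, 0.45), (39, 7)),
        "air": ((1.42, 0.25), (48, 7)),
        "co2": ((1.25, 0.26), (63, 18)),
    },
    "occipital_lobe": {
        "2cm/s": ((2.39, 0.48), (71, 11)),
        "3cm/s": ((2.30, 0.56), (71, 11)),
        "4cm/s": ((2.14, 0.26), (68, 12)),
        "air": ((1.76, 0.20), (67, 15)),
        "co2": ((1.50, 0.26), (96, 22)),
    },
    "parietal_lobe": {
        "2cm/s": ((2.38, 0.42), (66, 7)),
        "3cm/s": ((2.31, 0.52), (65, 9)),
        "4cm/s": ((2.15, 0.40), (63, 11)),
        "air": ((1.68, 0.20), (67, 14)),
        "co2": ((1.46, 0.25), (95, 20)),
    },
    "putamen": {
        "2cm/s": ((1.92, 0.76), (37, 11)),
        "3cm/s": ((2.03, 0.74), (36, 11)),
        "4cm/s": ((1.94, 0.80), (29, 11)),
        "air": ((1.44, 0.28), (40, 12)),
        "co2": ((1.25, 0.32), (52, 16)),
    },
    "temporal_lobe": {
        "2cm/s": ((2.05, 0.44), (53, 8)),
        "3cm/s": ((2.07, 0.53), (52, 7)),
        "4cm/s": ((2.01, 0.51), (50, 8)),
        "air": ((1.56, 0.23), (54, 11)),
        "co2": ((1.36, 0.24), (72, 14)),
    },
    "thalamus": {
        "2cm/s": ((2.65, 0.59), (63, 17)),
        "3cm/s": ((2.75, 0.76), (58, 14)),
        "4cm/s": ((2.24, 0.57), (55, 12)),
        "air": ((1.76, 0.21), (53, 15)),
        "co2": ((1.49, 0.27), (88, 23)),
    },
}

#: whole grey-matter row (not painted as a phantom region; used for
#: single-compartment round-trip checks and generator calibration)
GM_ROW: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "2cm/s": ((2.20, 0.35), (57, 8)),
    "3cm/s": ((2.22, 0.53), (56, 8)),
    "4cm/s": ((2.05, 0.34), (54, 9)),
    "air": ((1.65, 0.20), (58, 11)),
    "co2": ((1.43, 0.24), (83, 17)),
}

#: macrovascular bolus duration (mean, SD) per cut-off column; the
#: normocapnic macrovascular blood volume fraction is ~0.10 +/- 0.07 %.
MACRO_BOLUS = {
    "2cm/s": (1.22, 0.17),
    "3cm/s": (1.22, 0.11),
    "4cm/s": (1.21, 0.13),
    "air": (1.22, 0.11),
    "co2": (1.22, 0.11),
}
MACRO_BV_DIST = (1.0e-3, 0.7e-3)

#: hypercapnia / normocapnia scaling of the generator truth: CBF +45 %,
#: bolus duration shortened to 1.43/1.65 of baseline, macrovascular blood
#: volume 0.10 -> 0.15 %.
HYPERCAPNIA_CBF_SCALE = 1.45
HYPERCAPNIA_BOLUS_SCALE = 1.43 / 1.65
HYPERCAPNIA_MACRO_BV_SCALE = 1.5
PETCO2_DELTA_DIST = (8.3, 2.4)


@dataclass(frozen=True)
class ParamDist:
    """Normal distribution (truncated at zero by redrawing) for one parameter."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.mean <= 0:
            raise ValueError("mean must be strictly positive")

    def draw(self, rng: np.random.Generator, max_tries: int = 1000) -> float:
        if self.sd == 0:
            return self.mean
        for _ in range(max_tries):
            v = rng.normal(self.mean, self.sd)
            if v > 0:
                return float(v)
        raise RuntimeError("could not draw a positive value")


@dataclass(frozen=True)
class RegionSpec:
    """One phantom region: label id and parameter distributions.

    ``f`` is in ml/g/s (use ``ParamDist(cbf / 6000, ...)`` to enter CBF).
    """

    name: str
    label: int
    f: ParamDist
    bolus_duration: ParamDist
    macro_bv: ParamDist
    macro_bolus_duration: ParamDist


@dataclass(frozen=True)
class Condition:
    """Experimental condition as multiplicative scaling of the truth."""

    name: str
    cbf_scale: float = 1.0
    bolus_scale: float = 1.0
    macro_bv_scale: float = 1.0
    petco2_delta: ParamDist | None = None


@dataclass(frozen=True)
class PhantomSpec:
    """Layout and statistical structure of a synthetic study."""

    regions: tuple[RegionSpec, ...]
    grid: tuple[int, int, int] = (32, 32, 15)
    n_subjects: int = 1
    noise_sd: float = 0.001
    n_pairs_per_lct: int = 4
    seed: int = 0
    conditions: tuple[Condition, ...] = (Condition("normocapnia"),)
    m0_value: float = 1000.0

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if not 1 <= len(self.regions) <= 9:
            raise ValueError("between 1 and 9 regions supported")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_pairs_per_lct < 1:
            raise ValueError("n_pairs_per_lct must be >= 1")
        if len(self.grid) != 3 or min(self.grid[:2]) < 6 or self.grid[2] < 3:
            raise ValueError("grid must be 3-D, in-plane >= 6, >= 3 slices")


@dataclass
class Phantom:
    """Shared geometry plus per-subject ground-truth parameter maps."""

    spec: PhantomSpec
    atlas: np.ndarray
    region_pve: dict[int, np.ndarray]
    region_names: dict[int, str]
    gm_pve: np.ndarray
    m0: np.ndarray
    truths: list[dict[str, np.ndarray]]
    region_draws: list[dict[str, dict[str, float]]]


@dataclass
class StudyImage:
    """One subject, one condition: observed signal plus reference volumes."""

    dm: np.ndarray  # (nx, ny, nz, n_lct)
    m0: np.ndarray
    gm_pve: np.ndarray
    atlas: np.ndarray
    region_pve: dict[int, np.ndarray]
    region_names: dict[int, str]
    timing: AcquisitionTiming
    condition: str = "normocapnia"
    truth: dict[str, np.ndarray] | None = None


@dataclass
class SubjectData:
    subject_id: int
    images: dict[str, StudyImage]
    petco2_delta: float | None = None


@dataclass
class Cohort:
    subjects: list[SubjectData]
    spec: PhantomSpec
    timing: AcquisitionTiming


def _axis_weights(lo: int, hi: int, size: int) -> np.ndarray:
    """Partial-volume profile along one axis of a region box.

    Core voxels are 1.0; the outermost box voxel tapers to 0.6 and a
    one-voxel halo outside the box to 0.2, so both the 50 % grey-matter and
    25 % region thresholds bite at different radii.
    """
    w = np.zeros(size)
    w[lo:hi] = 1.0
    if hi - lo >= 3:
        w[lo] = w[hi - 1] = 0.6
    if lo - 1 >= 0:
        w[lo - 1] = 0.2
    if hi < size:
        w[hi] = 0.2
    return w


def _region_boxes(grid, n_regions):
    """Row-major 3x3 arrangement of disjoint in-plane boxes."""
    nx, ny, nz = grid
    n_cols = 1 if n_regions == 1 else (2 if n_regions <= 4 else 3)
    n_rows = math.ceil(n_regions / n_cols)
    cw, ch = nx // n_cols, ny // n_rows
    boxes = []
    for i in range(n_regions):
        r, c = divmod(i, n_cols)
        x0, y0 = c * cw + 1, r * ch + 1
        x1, y1 = min((c + 1) * cw - 1, nx - 1), min((r + 1) * ch - 1, ny - 1)
        if x1 - x0 < 2 or y1 - y0 < 2:
            raise ValueError("grid too small for the requested region count")
        boxes.append((x0, x1, y0, y1))
    return boxes


def make_phantom(spec: PhantomSpec, rng: np.random.Generator | None = None) -> Phantom:
    """Build geometry and draw per-subject, per-region ground truth."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid
    z0, z1 = 1, nz - 1
    boxes = _region_boxes(spec.grid, len(spec.regions))

    atlas = np.zeros(spec.grid, dtype=np.int16)
    region_pve: dict[int, np.ndarray] = {}
    region_names: dict[int, str] = {}
    gm_pve = np.zeros(spec.grid)
    for reg, (x0, x1, y0, y1) in zip(spec.regions, boxes):
        wx = _axis_weights(x0, x1, nx)
        wy = _axis_weights(y0, y1, ny)
        pve2d = np.minimum.outer(wx, wy)
        pve = np.zeros(spec.grid)
        pve[:, :, z0:z1] = pve2d[:, :, None]
        region_pve[reg.label] = pve
        region_names[reg.label] = reg.name
        atlas[pve > 0] = reg.label
        gm_pve = np.maximum(gm_pve, pve)

    m0 = np.full(spec.grid, 0.4 * spec.m0_value)
    m0[gm_pve > 0] = spec.m0_value
    # low-signal pocket inside the last region: fails the 50 %-of-max rule
    x0, x1, y0, y1 = boxes[-1]
    px = slice(x0 + 1, x0 + 1 + max(1, (x1 - x0) // 3))
    py = slice(y0 + 1, y0 + 1 + max(1, (y1 - y0) // 3))
    m0[px, py, z0:z1] = 0.3 * spec.m0_value

    truths: list[dict[str, np.ndarray]] = []
    region_draws: list[dict[str, dict[str, float]]] = []
    for _ in range(spec.n_subjects):
        maps = {
            key: np.zeros(spec.grid)
            for key in ("f", "bolus_duration", "macro_bv", "macro_bolus_duration")
        }
        draws: dict[str, dict[str, float]] = {}
        for reg in spec.regions:
            vals = {
                "f": reg.f.draw(rng),
                "bolus_duration": reg.bolus_duration.draw(rng),
                "macro_bv": reg.macro_bv.draw(rng),
                "macro_bolus_duration": reg.macro_bolus_duration.draw(rng),
            }
            inside = region_pve[reg.label] > 0
            for key, v in vals.items():
                maps[key][inside] = v
            draws[reg.name] = vals
        truths.append(maps)
        region_draws.append(draws)

    return Phantom(
        spec=spec,
        atlas=atlas,
        region_pve=region_pve,
        region_names=region_names,
        gm_pve=gm_pve,
        m0=m0,
        truths=truths,
        region_draws=region_draws,
    )


def _clean_signal(truth, m0, timing, consts, condition: Condition) -> np.ndarray:
    """Noise-free difference signal, slice by slice, at each LCT."""
    nx, ny, nz = m0.shape
    lct = np.asarray(timing.lct_values)
    out = np.empty((nx, ny, nz, lct.size))
    f = truth["f"] * condition.cbf_scale
    bolus = truth["bolus_duration"] * condition.bolus_scale
    mbv = truth["macro_bv"] * condition.macro_bv_scale
    tmac = truth["macro_bolus_duration"]
    for z in range(nz):
        t = timing.readout_times(z)
        out[:, :, z, :] = tissue_signal(
            f[:, :, z, None], bolus[:, :, z, None], m0[:, :, z, None], lct, t, consts
        ) + macro_signal(
            mbv[:, :, z, None], tmac[:, :, z, None], m0[:, :, z, None], t, consts
        )
    return out


def scaled_truth(truth: dict[str, np.ndarray], condition: Condition) -> dict[str, np.ndarray]:
    """Ground-truth maps with the condition scaling applied."""
    return {
        "f": truth["f"] * condition.cbf_scale,
        "bolus_duration": truth["bolus_duration"] * condition.bolus_scale,
        "macro_bv": truth["macro_bv"] * condition.macro_bv_scale,
        "macro_bolus_duration": truth["macro_bolus_duration"].copy(),
        "cbf": truth["f"] * condition.cbf_scale * CBF_SCALE,
    }


def simulate_study(
    phantom: Phantom,
    subject: int,
    timing: AcquisitionTiming,
    consts: PhysioConstants,
    condition: Condition | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
    n_pairs: int | None = None,
) -> StudyImage:
    """Observed difference-signal stack for one subject and condition.

    The observation is the mean over ``n_pairs`` tag/control pairs, each the
    clean signal plus Gaussian noise of SD ``noise_sd * M0 * sqrt(2)``.
    """
    spec = phantom.spec
    condition = condition or spec.conditions[0]
    noise_sd = spec.noise_sd if noise_sd is None else noise_sd
    n_pairs = spec.n_pairs_per_lct if n_pairs is None else n_pairs
    if timing.n_slices != spec.grid[2]:
        raise ValueError("timing.n_slices must equal the phantom slice count")

    truth = phantom.truths[subject]
    dm = _clean_signal(truth, phantom.m0, timing, consts, condition)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
        sd = noise_sd * math.sqrt(2.0) * phantom.m0[..., None]
        noise = rng.normal(0.0, 1.0, size=(n_pairs, *dm.shape)).mean(axis=0)
        dm = dm + noise * sd
    return StudyImage(
        dm=dm,
        m0=phantom.m0,
        gm_pve=phantom.gm_pve,
        atlas=phantom.atlas,
        region_pve=phantom.region_pve,
        region_names=phantom.region_names,
        timing=timing,
        condition=condition.name,
        truth=scaled_truth(truth, condition),
    )


def simulate_cohort(
    spec: PhantomSpec,
    timing: AcquisitionTiming,
    consts: PhysioConstants | None = None,
) -> Cohort:
    """Full deterministic study: phantom draws, signals, and PETCO2 deltas."""
    consts = consts or PhysioConstants()
    rng = np.random.default_rng(spec.seed)
    phantom = make_phantom(spec, rng)
    subjects = []
    for s in range(spec.n_subjects):
        images = {}
        petco2 = None
        for cond in spec.conditions:
            images[cond.name] = simulate_study(
                phantom, s, timing, consts, cond, rng
            )
            if cond.petco2_delta is not None:
                petco2 = cond.petco2_delta.draw(rng)
        subjects.append(SubjectData(subject_id=s, images=images, petco2_delta=petco2))
    return Cohort(subjects=subjects, spec=spec, timing=timing)


def _preset_regions(column: str) -> tuple[RegionSpec, ...]:
    regions = []
    for i, (name, cols) in enumerate(REGION_TABLE.items(), start=1):
        (bolus_m, bolus_sd), (cbf_m, cbf_sd) = cols[column]
        regions.append(
            RegionSpec(
                name=name,
                label=i,
                f=ParamDist(cbf_m / CBF_SCALE, cbf_sd / CBF_SCALE),
                bolus_duration=ParamDist(bolus_m, bolus_sd),
                macro_bv=ParamDist(*MACRO_BV_DIST),
                macro_bolus_duration=ParamDist(*MACRO_BOLUS[column]),
            )
        )
    return tuple(regions)


def gm_row(column: str, sd: bool = False) -> dict[str, ParamDist]:
    """Whole-grey-matter parameter distributions for one table column."""
    (bolus_m, bolus_sd), (cbf_m, cbf_sd) = GM_ROW[column]
    return {
        "f": ParamDist(cbf_m / CBF_SCALE, cbf_sd / CBF_SCALE if sd else 0.0),
        "bolus_duration": ParamDist(bolus_m, bolus_sd if sd else 0.0),
        "macro_bv": ParamDist(MACRO_BV_DIST[0], MACRO_BV_DIST[1] if sd else 0.0),
        "macro_bolus_duration": ParamDist(
            MACRO_BOLUS[column][0], MACRO_BOLUS[column][1] if sd else 0.0
        ),
    }


def experiment1_preset(
    v_cutoff: str = "2cm/s", **overrides
) -> tuple[PhantomSpec, AcquisitionTiming]:
    """Resting multi-LCT study: 11 LCTs up to 3.5 s, 13 subjects."""
    if v_cutoff not in ("2cm/s", "3cm/s", "4cm/s"):
        raise ValueError("v_cutoff must be one of 2cm/s, 3cm/s, 4cm/s")
    overrides.setdefault("n_subjects", 13)
    spec = PhantomSpec(regions=_preset_regions(v_cutoff), **overrides)
    timing = AcquisitionTiming(EXPERIMENT1_LCTS, n_slices=spec.grid[2])
    return spec, timing


def experiment2_preset(**overrides) -> tuple[PhantomSpec, AcquisitionTiming]:
    """Two-condition CVR study: 8 LCTs up to 2.0 s, 19 subjects."""
    conditions = (
        Condition("normocapnia"),
        Condition(
            "hypercapnia",
            cbf_scale=HYPERCAPNIA_CBF_SCALE,
            bolus_scale=HYPERCAPNIA_BOLUS_SCALE,
            macro_bv_scale=HYPERCAPNIA_MACRO_BV_SCALE,
            petco2_delta=ParamDist(*PETCO2_DELTA_DIST),
        ),
    )
    overrides.setdefault("conditions", conditions)
    overrides.setdefault("n_subjects", 19)
    spec = PhantomSpec(regions=_preset_regions("air"), **overrides)
    timing = AcquisitionTiming(EXPERIMENT2_LCTS, n_slices=spec.grid[2])
    return spec, timing
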
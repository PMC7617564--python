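"""File formats: NIfTI volumes, YAML configuration, CSV summaries.

Volumes are written single-precision (labels as int16); computation is done
in double precision.  Study directories are self-describing: a ``study.json``
sidecar records timing, conditions, PETCO2 deltas and provenance, with one
subdirectory per subject.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import MaskSpec, RegionSummary
from .model import AcquisitionTiming, PhysioConstants
from .synthetic import (
    Cohort,
    Condition,
    ParamDist,
    PhantomSpec,
    RegionSpec,
    StudyImage,
    SubjectData,
)

__all__ = [
    "read_volume",
    "write_volume",
    "write_study",
    "read_study",
    "write_region_summary",
    "write_provenance",
    "RunConfig",
    "load_config",
]

_TRUTH_KEYS = ("f", "bolus_duration", "macro_bv", "macro_bolus_duration", "cbf")


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI image as (float64 data, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def write_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a volume as NIfTI-1; floats stored single precision."""
    data = np.asarray(data)
    if affine is None:
        affine = np.eye(4)
    dtype = np.int16 if np.issubdtype(data.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(data.astype(dtype), affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def _timing_dict(t: AcquisitionTiming) -> dict:
    return {
        "lct_values": list(t.lct_values),
        "crusher_to_readout": t.crusher_to_readout,
        "slice_delay": t.slice_delay,
        "n_slices": t.n_slices,
    }


def write_study(cohort: Cohort, outdir) -> Path:
    """Serialise a cohort to a study directory of NIfTI + JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "software_version": __version__,
        "seed": cohort.spec.seed,
        "noise_sd": cohort.spec.noise_sd,
        "n_pairs_per_lct": cohort.spec.n_pairs_per_lct,
        "timing": _timing_dict(cohort.timing),
        "conditions": [c.name for c in cohort.spec.conditions],
        "region_labels": {},
        "subjects": [],
    }
    for subj in cohort.subjects:
        sdir = outdir / f"sub-{subj.subject_id + 1:02d}"
        first = next(iter(subj.images.values()))
        meta["region_labels"] = {
            str(k): v for k, v in first.region_names.items()
        }
        write_volume(first.m0, sdir / "m0.nii")
        write_volume(first.gm_pve, sdir / "gm_pve.nii")
        write_volume(first.atlas.astype(np.int16), sdir / "atlas.nii")
        for label, pve in first.region_pve.items():
            write_volume(pve, sdir / f"pve_region-{label}.nii")
        for cname, img in subj.images.items():
            write_volume(img.dm, sdir / f"dm_{cname}.nii")
            if img.truth is not None:
                for key in _TRUTH_KEYS:
                    write_volume(img.truth[key], sdir / f"truth_{cname}_{key}.nii")
        meta["subjects"].append(
            {"id": subj.subject_id, "petco2_delta": subj.petco2_delta}
        )
    (outdir / "study.json").write_text(json.dumps(meta, indent=2))
    return outdir


def read_study(indir) -> Cohort:
    """Load a study directory written by :func:`write_study`."""
    indir = Path(indir)
    meta_path = indir / "study.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a study directory (no study.json): {indir}")
    meta = json.loads(meta_path.read_text())
    timing = AcquisitionTiming(
        tuple(meta["timing"]["lct_values"]),
        meta["timing"]["crusher_to_readout"],
        meta["timing"]["slice_delay"],
        meta["timing"]["n_slices"],
    )
    region_names = {int(k): v for k, v in meta["region_labels"].items()}
    subjects = []
    for entry in meta["subjects"]:
        sdir = indir / f"sub-{entry['id'] + 1:02d}"
        m0, _ = read_volume(sdir / "m0.nii")
        gm_pve, _ = read_volume(sdir / "gm_pve.nii")
        atlas, _ = read_volume(sdir / "atlas.nii")
        atlas = atlas.astype(np.int16)
        region_pve = {
            label: read_volume(sdir / f"pve_region-{label}.nii")[0]
            for label in region_names
        }
        images = {}
        for cname in meta["conditions"]:
            dm, _ = read_volume(sdir / f"dm_{cname}.nii")
            truth = None
            truth_path = sdir / f"truth_{cname}_f.nii"
            if truth_path.exists():
                truth = {
                    key: read_volume(sdir / f"truth_{cname}_{key}.nii")[0]
                    for key in _TRUTH_KEYS
                }
            images[cname] = StudyImage(
                dm=dm,
                m0=m0,
                gm_pve=gm_pve,
                atlas=atlas,
                region_pve=region_pve,
                region_names=region_names,
                timing=timing,
                condition=cname,
                truth=truth,
            )
        subjects.append(
            SubjectData(
                subject_id=entry["id"],
                images=images,
                petco2_delta=entry["petco2_delta"],
            )
        )
    # reconstruct a minimal spec; region distributions are not round-tripped
    grid = subjects[0].images[meta["conditions"][0]].m0.shape
    spec = PhantomSpec(
        regions=tuple(
            RegionSpec(
                name=name,
                label=label,
                f=ParamDist(1e-2),
                bolus_duration=ParamDist(1.0),
                macro_bv=ParamDist(1e-3),
                macro_bolus_duration=ParamDist(1.0),
            )
            for label, name in region_names.items()
        ),
        grid=grid,
        n_subjects=len(subjects),
        noise_sd=meta["noise_sd"],
        n_pairs_per_lct=meta["n_pairs_per_lct"],
        seed=meta["seed"],
        conditions=tuple(Condition(c) for c in meta["conditions"]),
    )
    return Cohort(subjects=subjects, spec=spec, timing=timing)


def write_region_summary(summaries: list[RegionSummary], path, cvr=None) -> None:
    """Region table: one row per region, group mean/SD columns per parameter.

    ``cvr`` optionally maps region name -> (mean, sd) CVR in %/mmHg.
    """
    rows = []
    for s in summaries:
        row = {"region": s.region, "n_subjects": s.n_subjects}
        for key in ("bolus_duration", "cbf", "macro_bv", "macro_bolus_duration"):
            row[f"{key}_mean"] = s.group_mean.get(key, math.nan)
            row[f"{key}_sd"] = s.group_sd.get(key, math.nan)
        if cvr is not None:
            row["cvr_mean"], row["cvr_sd"] = cvr.get(s.region, (math.nan, math.nan))
        rows.append(row)
    columns = ["region", "n_subjects"]
    for key in ("bolus_duration", "cbf", "macro_bv", "macro_bolus_duration"):
        columns += [f"{key}_mean", f"{key}_sd"]
    if cvr is not None:
        columns += ["cvr_mean", "cvr_sd"]
    df = pd.DataFrame(rows, columns=columns)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")


def write_provenance(path, **entries) -> None:
    """JSON sidecar with constants, thresholds, seed and software version."""
    payload = {"software_version": __version__}
    payload.update(entries)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)


@dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML file."""

    physio: PhysioConstants
    timing: AcquisitionTiming | None
    mask: MaskSpec
    phantom: PhantomSpec | None
    seed: int


def _strict(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def _dist(value) -> ParamDist:
    if isinstance(value, (int, float)):
        return ParamDist(float(value))
    return ParamDist(float(value["mean"]), float(value.get("sd", 0.0)))


def load_config(path) -> RunConfig:
    """Parse and validate a YAML configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    _strict(raw, {"physio", "timing", "mask", "phantom", "seed"}, "config")

    physio_raw = raw.get("physio", {}) or {}
    _strict(
        physio_raw,
        {"alpha", "alpha_bgs", "t1_blood", "t1_tissue", "lambda_bt"},
        "physio",
    )
    physio = PhysioConstants(**physio_raw)

    timing = None
    if "timing" in raw:
        timing_raw = raw["timing"]
        _strict(
            timing_raw,
            {"lct_values", "crusher_to_readout", "slice_delay", "n_slices"},
            "timing",
        )
        timing_raw = dict(timing_raw)
        timing_raw["lct_values"] = tuple(timing_raw["lct_values"])
        timing = AcquisitionTiming(**timing_raw)

    mask_raw = raw.get("mask", {}) or {}
    _strict(
        mask_raw,
        {"gm_pve_threshold", "m0_fraction_threshold", "region_pve_threshold"},
        "mask",
    )
    mask = MaskSpec(**mask_raw)

    phantom = None
    if "phantom" in raw:
        ph = dict(raw["phantom"])
        _strict(
            ph,
            {
                "grid",
                "regions",
                "n_subjects",
                "noise_sd",
                "n_pairs_per_lct",
                "conditions",
                "m0_value",
            },
            "phantom",
        )
        regions = []
        for i, reg in enumerate(ph.pop("regions"), start=1):
            _strict(
                reg,
                {"name", "label", "f", "cbf", "bolus_duration", "macro_bv",
                 "macro_bolus_duration"},
                f"phantom.regions[{i - 1}]",
            )
            if ("f" in reg) == ("cbf" in reg):
                raise ValueError("give exactly one of 'f' (ml/g/s) or 'cbf'")
            if "cbf" in reg:
                d = _dist(reg["cbf"])
                f = ParamDist(d.mean / 6000.0, d.sd / 6000.0)
            else:
                f = _dist(reg["f"])
            regions.append(
                RegionSpec(
                    name=reg["name"],
                    label=int(reg.get("label", i)),
                    f=f,
                    bolus_duration=_dist(reg["bolus_duration"]),
                    macro_bv=_dist(reg["macro_bv"]),
                    macro_bolus_duration=_dist(reg["macro_bolus_duration"]),
                )
            )
        conditions = []
        for cond in ph.pop("conditions", [{"name": "normocapnia"}]):
            _strict(
                cond,
                {"name", "cbf_scale", "bolus_scale", "macro_bv_scale",
                 "petco2_delta"},
                "phantom.conditions",
            )
            petco2 = cond.get("petco2_delta")
            conditions.append(
                Condition(
                    name=cond["name"],
                    cbf_scale=float(cond.get("cbf_scale", 1.0)),
                    bolus_scale=float(cond.get("bolus_scale", 1.0)),
                    macro_bv_scale=float(cond.get("macro_bv_scale", 1.0)),
                    petco2_delta=_dist(petco2) if petco2 is not None else None,
                )
            )
        if "grid" in ph:
            ph["grid"] = tuple(ph["grid"])
        phantom = PhantomSpec(
            regions=tuple(regions),
            conditions=tuple(conditions),
            seed=int(raw.get("seed", 0)),
            **ph,
        )

    return RunConfig(
        physio=physio,
        timing=timing,
        mask=mask,
        phantom=phantom,
        seed=int(raw.get("seed", 0)),
    )
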
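"""Closed-form forward model for the velocity-selective ASL difference signal.

The measured signal is the sum of a tissue compartment -- a single-compartment
kinetic model with instantaneous bolus arrival and a vascular-crusher-defined
effective bolus duration -- and a residual macrovascular compartment that
decays with blood T1 and vanishes abruptly once the macrovascular bolus has
cleared.

Only the post-delivery branch of the kinetic model is implemented: the readout
always follows the crusher module, so the label-to-readout time ``t`` exceeds
the label-to-crusher time (LCT) and therefore exceeds the effective bolus
duration.  The inflow branch (``t`` < bolus duration) is deliberately absent.

All functions broadcast over numpy arrays.  Perfusion ``f`` is carried
internally in ml/g/s; conversion to the conventional ml/100 g/min happens only
at reporting time via :data:`CBF_SCALE`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CBF_SCALE",
    "PhysioConstants",
    "AcquisitionTiming",
    "TissueParams",
    "readout_time",
    "t1_apparent",
    "decay_rate",
    "qp_factor",
    "tissue_signal",
    "macro_signal",
    "delta_m_tissue",
    "delta_m_macro",
    "delta_m_total",
    "model_curve",
]

#: ml/g/s -> ml/100 g/min
CBF_SCALE = 6000.0

#: |k * tau| below which the removable singularity of qp is bridged by series.
_K_TAU_EPS = 1e-6


@dataclass(frozen=True)
class PhysioConstants:
    """Fixed physiological scalars of the signal model.

    Parameters
    ----------
    alpha
        Inversion (labelling) efficiency, dimensionless.
    alpha_bgs
        Signal attenuation from the background-suppression pulses,
        dimensionless.
    t1_blood
        Longitudinal relaxation time of arterial blood, seconds.
    t1_tissue
        Longitudinal relaxation time of tissue, seconds.
    lambda_bt
        Blood--tissue partition coefficient, ml/g.
    """

    alpha: float = 0.56
    alpha_bgs: float = 0.86
    t1_blood: float = 1.6
    t1_tissue: float = 1.3
    lambda_bt: float = 0.9

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_bgs", "t1_blood", "t1_tissue", "lambda_bt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha > 1 or self.alpha_bgs > 1:
            raise ValueError("alpha and alpha_bgs must be <= 1")


@dataclass(frozen=True)
class AcquisitionTiming:
    """Label-to-crusher times and readout-delay geometry.

    ``crusher_to_readout`` is the delay between the vascular crushing module
    and the first slice of the 2D readout; each ascending slice adds a further
    ``slice_delay``.
    """

    lct_values: tuple[float, ...]
    crusher_to_readout: float = 0.050
    slice_delay: float = 0.0425
    n_slices: int = 15

    def __post_init__(self) -> None:
        lct = np.asarray(self.lct_values, dtype=float)
        if lct.ndim != 1 or lct.size == 0:
            raise ValueError("lct_values must be a non-empty 1-D sequence")
        if not np.all(lct > 0):
            raise ValueError("lct_values must be strictly positive")
        if not np.all(np.diff(lct) > 0):
            raise ValueError("lct_values must be strictly increasing")
        if self.crusher_to_readout < 0 or self.slice_delay < 0:
            raise ValueError("readout delays must be non-negative")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        object.__setattr__(self, "lct_values", tuple(float(v) for v in lct))

    @property
    def max_lct(self) -> float:
        return self.lct_values[-1]

    def readout_times(self, slice_index: int) -> np.ndarray:
        """Label-to-readout time for every LCT at one slice."""
        self._check_slice(slice_index)
        lct = np.asarray(self.lct_values)
        return lct + self.crusher_to_readout + slice_index * self.slice_delay

    def _check_slice(self, slice_index: int) -> None:
        if not 0 <= slice_index < self.n_slices:
            raise ValueError(
                f"slice_index {slice_index} outside [0, {self.n_slices})"
            )

    def truncated(self, max_lct: float) -> "AcquisitionTiming":
        """Timing restricted to LCTs <= ``max_lct`` (other geometry kept)."""
        kept = tuple(v for v in self.lct_values if v <= max_lct + 1e-12)
        if not kept:
            raise ValueError("no LCT values remain after truncation")
        return AcquisitionTiming(
            kept, self.crusher_to_readout, self.slice_delay, self.n_slices
        )


@dataclass
class TissueParams:
    """The fitted quantities of one voxel.

    ``f`` is perfusion in ml/g/s (multiply by :data:`CBF_SCALE` for
    ml/100 g/min).  ``macro_bv`` is the apparent macrovascular blood volume
    fraction surviving the crusher.  No sign constraint is imposed on ``f`` or
    ``macro_bv``: the fit is unconstrained and signs are handled post hoc.
    """

    f: float
    bolus_duration: float
    macro_bv: float = 0.0
    macro_bolus_duration: float = 0.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not self.m0 > 0:
            raise ValueError("m0 must be strictly positive")

    @property
    def cbf(self) -> float:
        """Perfusion in ml/100 g/min."""
        return self.f * CBF_SCALE


def readout_time(lct, slice_index: int, timing: AcquisitionTiming):
    """Label-to-readout time ``t`` for a given LCT and slice."""
    timing._check_slice(slice_index)
    return (
        np.asarray(lct, dtype=float)
        + timing.crusher_to_readout
        + slice_index * timing.slice_delay
    )


def t1_apparent(f, consts: PhysioConstants):
    """Apparent tissue T1: 1/T1' = 1/T1_tissue + f/lambda."""
    return 1.0 / (1.0 / consts.t1_tissue + np.asarray(f, dtype=float) / consts.lambda_bt)


def decay_rate(f, consts: PhysioConstants):
    """Rate constant k = 1/T1_blood - 1/T1'."""
    return (
        1.0 / consts.t1_blood
        - 1.0 / consts.t1_tissue
        - np.asarray(f, dtype=float) / consts.lambda_bt
    )


def _bridged_ratio(x):
    """(1 - exp(-x)) / x with the removable singularity at x = 0 bridged."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _K_TAU_EPS
    safe = np.where(small, 1.0, x)
    out = -np.expm1(-safe) / safe
    # second-order series: 1 - x/2 + x^2/6
    series = 1.0 - x / 2.0 + x * x / 6.0
    return np.where(small, series, out)


def qp_factor(f, tau_eff, t, consts: PhysioConstants):
    """Correction factor q_p = exp(k t) (1 - exp(-k tau)) / (k tau).

    Accounts for the difference between blood and apparent tissue relaxation.
    ``tau_eff`` must be strictly positive and ``t >= tau_eff``.
    """
    tau_eff = np.asarray(tau_eff, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(tau_eff <= 0):
        raise ValueError("tau_eff must be strictly positive")
    if np.any(t < tau_eff):
        raise ValueError("t must be >= tau_eff (post-delivery branch only)")
    k = decay_rate(f, consts)
    return np.exp(k * t) * _bridged_ratio(k * tau_eff)


def tissue_signal(f, bolus_duration, m0, lct, t, consts: PhysioConstants):
    """Tissue-compartment difference signal (array-friendly core).

    dM = 2 alpha alpha_bgs f tau_eff M0 exp(-t/T1_blood) q_p, with
    tau_eff = min(bolus_duration, LCT).  Zero wherever ``f`` or the bolus
    duration is zero (or negative, which only arises transiently during
    unconstrained searches).
    """
    f = np.asarray(f, dtype=float)
    bolus = np.asarray(bolus_duration, dtype=float)
    lct = np.asarray(lct, dtype=float)
    t = np.asarray(t, dtype=float)
    tau_eff = np.minimum(bolus, lct)
    live = (tau_eff > 0) & (f != 0)
    tau_safe = np.where(tau_eff > 0, tau_eff, 1.0)
    k = decay_rate(f, consts)
    qp = np.exp(k * t) * _bridged_ratio(k * tau_safe)
    amp = 2.0 * consts.alpha * consts.alpha_bgs
    sig = amp * f * tau_safe * np.asarray(m0, dtype=float)
    sig = sig * np.exp(-t / consts.t1_blood) * qp
    return np.where(live, sig, 0.0)


def macro_signal(macro_bv, macro_bolus_duration, m0, t, consts: PhysioConstants):
    """Macrovascular difference signal: step trailing edge at tau_macro."""
    t = np.asarray(t, dtype=float)
    amp = 2.0 * consts.alpha * consts.alpha_bgs
    sig = amp * np.asarray(macro_bv, dtype=float) * np.asarray(m0, dtype=float)
    sig = sig * np.exp(-t / consts.t1_blood)
    return np.where(t <= np.asarray(macro_bolus_duration, dtype=float), sig, 0.0)


def delta_m_tissue(params: TissueParams, lct, t, consts: PhysioConstants):
    """Tissue-compartment signal for one parameter set.

    ``t`` must not precede the crusher (``t >= lct``).
    """
    if np.any(np.asarray(t, dtype=float) < np.asarray(lct, dtype=float)):
        raise ValueError("t must be >= lct (readout follows the crusher)")
    return tissue_signal(params.f, params.bolus_duration, params.m0, lct, t, consts)


def delta_m_macro(params: TissueParams, t, consts: PhysioConstants):
    """Macrovascular signal for one parameter set."""
    if np.any(np.asarray(t, dtype=float) <= 0):
        raise ValueError("t must be strictly positive")
    return macro_signal(
        params.macro_bv, params.macro_bolus_duration, params.m0, t, consts
    )


def delta_m_total(
    params: TissueParams,
    lct,
    slice_index: int,
    timing: AcquisitionTiming,
    consts: PhysioConstants,
):
    """Tissue + macrovascular signal at the slice's readout time."""
    t = readout_time(lct, slice_index, timing)
    return delta_m_tissue(params, lct, t, consts) + delta_m_macro(params, t, consts)


def model_curve(
    params: TissueParams,
    timing: AcquisitionTiming,
    slice_index: int,
    consts: PhysioConstants,
) -> np.ndarray:
    """Predicted signal at every LCT of ``timing`` for one slice."""
    lct = np.asarray(timing.lct_values)
    return delta_m_total(params, lct, slice_index, timing, consts)
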
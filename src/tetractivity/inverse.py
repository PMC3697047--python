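"""Inverse-problem reduction: from Ago affinities to cell abundance.

Total miRNA abundance is, in the linear-additive picture, a weighted sum
of the miRNA's occupancies of all four Argonaute proteins.  Only the
Ago2 and Ago3 affinities can be estimated from sequence, so recovering
abundance is ill-posed.  The reduction implemented here:

1. a heuristic Ago2-availability estimate ``kappa * x2 - x3`` where the
   normalization factor kappa reflects the measurement conditions (1/3
   under normal growth, where Ago2 also acts outside RISC; 1/2 under
   actinomycin-D transcription arrest, where Ago2-mediated biogenesis
   stops) and the ``- x3`` term penalizes competition by Ago3;
2. a parameter-free range calibration mapping the estimate's (min, max)
   onto the observed abundance range — a linear map ``gamma * v +
   delta`` fixed entirely by the two ranges, with no least squares;
3. composition with the Ago affinity model, yielding a linear abundance
   model over the (RHHK, YRHB) features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import AGO2_EQ5, AGO3_EQ5, PublishedModel

DEFAULT_KAPPAS = {"normal": 1.0 / 3.0, "actinomycin": 1.0 / 2.0}


@dataclass(frozen=True)
class RangeCalibration:
    """The linear map sending a source range onto a target range."""

    gamma: float
    delta: float
    source_range: tuple[float, float]
    target_range: tuple[float, float]

    def apply(self, v):
        return self.gamma * np.asarray(v, dtype=float) + self.delta


@dataclass(frozen=True)
class InverseConfig:
    kappa: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.kappa > 1:
            raise ValueError(f"kappa must be in (0, 1], got {self.kappa}")
        if not any(np.isclose(self.kappa, k) for k in DEFAULT_KAPPAS.values()):
            warnings.warn(
                f"non-standard kappa {self.kappa}; the calibrated conditions use "
                "1/3 (normal) or 1/2 (transcription arrest)",
                stacklevel=2,
            )


def ago2_availability(x2: float, x3: float, kappa: float = 1.0 / 3.0) -> float:
    """Heuristic available-Ago2 estimate ``kappa * x2 - x3``."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return kappa * x2 - x3


def calibrate(source, target) -> RangeCalibration:
    """Match the source range onto the target range by its endpoints.

    No optimization: gamma and delta are forced by requiring
    min(source) -> min(target) and max(source) -> max(target).
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.size < 2 or t.size < 2:
        raise ValueError("need at least 2 values on each side")
    s_lo, s_hi = float(s.min()), float(s.max())
    t_lo, t_hi = float(t.min()), float(t.max())
    if s_hi == s_lo:
        raise ValueError("source range is degenerate")
    gamma = (t_hi - t_lo) / (s_hi - s_lo)
    delta = t_lo - gamma * s_lo
    return RangeCalibration(gamma=gamma, delta=delta,
                            source_range=(s_lo, s_hi), target_range=(t_lo, t_hi))


def calibrate_moments(source, target) -> RangeCalibration:
    """Alternative calibration matching mean and standard deviation."""
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.std() == 0:
        raise ValueError("source spread is degenerate")
    gamma = float(t.std(ddof=1) / s.std(ddof=1))
    delta = float(t.mean() - gamma * s.mean())
    return RangeCalibration(gamma=gamma, delta=delta,
                            source_range=(float(s.min()), float(s.max())),
                            target_range=(float(t.min()), float(t.max())))


def build_condition_model(
    config: InverseConfig,
    calib: RangeCalibration,
    ago2: PublishedModel = AGO2_EQ5,
    ago3: PublishedModel = AGO3_EQ5,
) -> PublishedModel:
    """Compose affinity model -> availability -> calibration into one
    linear abundance model over the (rhhk, yrhb) features.

    With kappa the availability factor and (gamma, delta) the range
    calibration, the slope on each feature is
    ``gamma * (kappa * a2 - a3)`` for the respective Ago2/Ago3
    coefficients a2, a3, and the intercept is
    ``gamma * (kappa * b2 - b3) + delta``.
    """
    k, g = config.kappa, calib.gamma
    names = sorted(set(ago2.coefficients) | set(ago3.coefficients))
    coefficients = {
        name: g * (k * ago2.coefficients.get(name, 0.0) - ago3.coefficients.get(name, 0.0))
        for name in names
    }
    intercept = g * (k * ago2.intercept - ago3.intercept) + calib.delta
    label = config.condition or f"kappa={config.kappa:g}"
    return PublishedModel(
        name=f"CONDITION({label},gamma={calib.gamma:g},delta={calib.delta:g})",
        intercept=intercept,
        coefficients=coefficients,
    )
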
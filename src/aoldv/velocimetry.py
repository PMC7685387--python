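"""Absolute maximum RBC velocity from the bidirectional Doppler geometry.

The cutoff-frequency difference between the two detection channels gives the
centreline velocity independently of the (unknown) incident scattering
geometry:

    vmax = lambda * |fA - fB| / (n * alpha * cos(beta))

with laser wavelength ``lambda``, plasma refractive index ``n``, inter-beam
angle ``alpha = arctan(x/L)`` and residual alignment angle ``beta`` (zero for
a well-aligned measurement).  ``alpha`` always uses the assumed axial length
common to all subjects; a subject's measured length enters only the image
pixel calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import OpticalConfig, scattering_angle
from .errors import InvalidGeometryError, InvalidInputError

__all__ = ["VelocityEstimate", "compute_vmax", "invert_vmax_to_delta_f"]


@dataclass(frozen=True)
class VelocityEstimate:
    """Maximum RBC velocity for one frame, with the geometry that produced it."""

    vmax: float  # m/s
    delta_f: float  # Hz
    alpha: float  # rad
    beta: float  # rad
    frame_index: int = 0

    @property
    def vmax_mm_s(self) -> float:
        return self.vmax * 1e3


def _geometry(config: OpticalConfig, axial_length_mm: float | None, beta: float):
    if abs(beta) >= math.pi / 2:
        raise InvalidGeometryError("|beta| must be < 90 degrees")
    alpha = scattering_angle(config, axial_length_mm)
    if alpha <= 0:
        raise InvalidGeometryError("scattering angle must be positive (x > 0)")
    return alpha


def compute_vmax(
    delta_f: float,
    config: OpticalConfig,
    axial_length_mm: float | None = None,
    beta: float = 0.0,
    frame_index: int = 0,
) -> VelocityEstimate:
    """Centreline velocity from the cutoff-frequency difference, in m/s.

    ``beta`` is in radians and defaults to 0 (the instrument aligns the
    detection plane with the vessel); pass a nonzero value only for
    sensitivity studies.
    """
    if delta_f < 0:
        raise InvalidInputError("delta_f must be non-negative")
    alpha = _geometry(config, axial_length_mm, beta)
    vmax = config.wavelength * delta_f / (config.refractive_index * alpha * math.cos(beta))
    return VelocityEstimate(
        vmax=vmax, delta_f=delta_f, alpha=alpha, beta=beta, frame_index=frame_index
    )


def invert_vmax_to_delta_f(
    vmax: float,
    config: OpticalConfig,
    axial_length_mm: float | None = None,
    beta: float = 0.0,
) -> float:
    """Cutoff-frequency difference (Hz) that yields a prescribed vmax (m/s).

    Exact inverse of :func:`compute_vmax`; used by the simulator to place
    channel cutoffs for a ground-truth velocity.
    """
    if vmax < 0:
        raise InvalidInputError("vmax must be non-negative")
    alpha = _geometry(config, axial_length_mm, beta)
    return vmax * config.refractive_index * alpha * math.cos(beta) / config.wavelength
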
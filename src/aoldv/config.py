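"""Optical/geometric configuration and the elementary geometry of bidirectional LDV.

The instrument measures absolute red-blood-cell velocity from the difference of
the Doppler cutoff frequencies seen along two detection directions separated by
a small angle ``alpha`` at the eye.  ``alpha = arctan(x / L)`` where ``x`` is the
separation of the two detection apertures at the pupil and ``L`` the axial eye
length.  A residual angle ``beta`` between the flow vector and the detection
plane inflates the apparent velocity by ``1 / cos(beta)``.

Units are SI internally (m, s, Hz); the axial length is carried in millimetres
because every formula that consumes it is written in millimetres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .errors import InvalidGeometryError, InvalidInputError

__all__ = [
    "OpticalConfig",
    "load_config",
    "scattering_angle",
    "beta_error_factor",
    "axial_length_sensitivity",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and acquisition parameters shared by all pipeline stages.

    Parameters
    ----------
    wavelength : float
        Probing-laser wavelength in metres (near-infrared source).
    refractive_index : float
        Refractive index of the medium surrounding the scatterers
        (blood plasma; 1.33, the standard value for aqueous media at NIR).
    beam_separation_x : float
        Distance in metres between the two detection apertures at the pupil
        plane.  Default 2.4 mm keeps Doppler shifts of physiological
        velocities well inside the 60 kHz Nyquist band.
    axial_length_assumed : float
        Axial eye length in millimetres used for the scattering angle,
        identical for all subjects (population average 23.95 mm).
    sampling_rate : float
        Detector sampling rate in Hz.
    doppler_window : float
        Duration in seconds of one Doppler acquisition window per frame.
    frames_per_acquisition : int
        Number of paired (image, spectrum) frames in one recording.
    calib_a, calib_b, calib_c : float
        Fundus-camera pixel calibration constants: ``n`` pixels map to
        ``n * calib_a * (L - calib_b) / calib_c`` micrometres at axial
        length ``L`` mm.
    """

    wavelength: float = 830e-9
    refractive_index: float = 1.33
    beam_separation_x: float = 2.4e-3
    axial_length_assumed: float = 23.95
    sampling_rate: float = 120_000.0
    doppler_window: float = 0.030
    frames_per_acquisition: int = 40
    calib_a: float = 19.269
    calib_b: float = 1.82
    calib_c: float = 373.87

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise InvalidInputError("wavelength must be positive")
        if self.refractive_index < 1:
            raise InvalidInputError("refractive_index must be >= 1")
        if self.beam_separation_x <= 0:
            raise InvalidInputError("beam_separation_x must be positive")
        if self.axial_length_assumed <= self.calib_b:
            raise InvalidInputError(
                f"axial_length_assumed must exceed {self.calib_b} mm"
            )
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")
        if self.doppler_window <= 0:
            raise InvalidInputError("doppler_window must be positive")
        if self.frames_per_acquisition < 1:
            raise InvalidInputError("frames_per_acquisition must be >= 1")

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz."""
        return self.sampling_rate / 2.0

    @property
    def window_samples(self) -> int:
        """Number of detector samples in one Doppler window."""
        return round(self.doppler_window * self.sampling_rate)

    @property
    def bin_width(self) -> float:
        """Spectral bin width in Hz of a single-window periodogram."""
        return 1.0 / self.doppler_window

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> OpticalConfig:
    """Build an :class:`OpticalConfig` from a YAML/JSON file plus overrides.

    Unknown keys in the file raise :class:`InvalidInputError`; keyword
    overrides win over file values.
    """
    fields: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise InvalidInputError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(OpticalConfig.__dataclass_fields__)
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        fields.update(data)
    fields.update({k: v for k, v in overrides.items() if v is not None})
    return OpticalConfig(**fields)


def scattering_angle(config: OpticalConfig, axial_length_mm: float | None = None) -> float:
    """Angle between the two detection directions at the eye, in radians.

    ``alpha = arctan(x / L)`` with the aperture separation ``x`` and the axial
    eye length ``L`` expressed in the same unit before division.  By default
    the configured assumed axial length is used.
    """
    if axial_length_mm is None:
        axial_length_mm = config.axial_length_assumed
    if axial_length_mm <= 0:
        raise InvalidInputError("axial length must be positive")
    return math.atan(config.beam_separation_x / (axial_length_mm * 1e-3))


def beta_error_factor(beta_deg: float) -> float:
    """Relative velocity inflation ``1/cos(beta) - 1`` incurred by ignoring beta.

    ``beta`` is the angle (degrees) between the flow vector and the detection
    plane.  Even in beta; 0 at beta = 0; e.g. 10 degrees inflates the velocity
    by about 1.5 %.
    """
    if abs(beta_deg) >= 90.0:
        raise InvalidGeometryError("|beta| must be < 90 degrees")
    return 1.0 / math.cos(math.radians(beta_deg)) - 1.0


def axial_length_sensitivity(config: OpticalConfig, delta_L_mm: float) -> float:
    """Relative change in computed flow from perturbing the assumed axial length.

    Only the scattering angle depends on the assumed length, and velocity (hence
    flow) is proportional to ``1/alpha``, so the relative change is
    ``alpha(L) / alpha(L + dL) - 1``.  For ``x << L`` this approaches
    ``dL / L`` (about 4 % per mm at L = 23.95 mm).
    """
    L = config.axial_length_assumed
    if L + delta_L_mm <= 0:
        raise InvalidInputError("perturbed axial length must be positive")
    return scattering_angle(config, L) / scattering_angle(config, L + delta_L_mm) - 1.0
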
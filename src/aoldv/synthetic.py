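"""Synthetic ground-truth generators for every pipeline stage.

Doppler side: for Poiseuille flow with uniformly distributed scatterers the
shift of a scatterer at radius ``r`` is ``f_cut * (1 - r^2/R^2)``, and a
uniform density over the cross-section makes the shift uniform on
``[0, f_cut]`` — the flat "step" spectrum.  Detector records are therefore
sums of unit tones with random phases and frequencies drawn uniformly up to
the channel cutoff, plus white Gaussian noise at a prescribed SNR.  The two
channel cutoffs differ by exactly the Doppler difference corresponding to the
requested ground-truth velocity.

Capillary (in-vitro) mode additionally weights tone amplitudes by a Gaussian
beam profile across the capillary: the beam is brightest on the axis, where
the fastest scatterers sit, enhancing the spectrum just below the cutoff;
total spectral power is normalised to be independent of velocity.

Image side: fundus phantoms are a quadratic illumination surface minus a dark
vessel band (Gaussian-smoothed bar cross-section whose half-depth width
equals the nominal diameter) plus a bright Gaussian probing-beam spot
(~31 px FWHM, i.e. ~50 um), plus white noise, clipped to 16 bits.

All randomness flows from one explicit integer seed through splittable
``numpy`` seed sequences; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .config import OpticalConfig
from .diameter import FundusImage, um_to_pixels
from .errors import InvalidInputError, InvalidScenarioError
from .flow import compute_flow, flow_to_vmax
from .spectra import DetectorRecord, PowerSpectrum, compute_power_spectrum
from .velocimetry import invert_vmax_to_delta_f

__all__ = [
    "SpectrumScenario",
    "ImageScenario",
    "BifurcationScenario",
    "VesselAcquisition",
    "simulate_detector_record",
    "simulate_capillary_spectrum",
    "simulate_fundus_image",
    "simulate_bifurcation",
    "make_conserved_bifurcation",
]

DEFAULT_N_TONES = 2000
SPOT_FWHM_PX = 31.0  # ~50 um probing beam at the fundus
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic 31-bit child seeds from one parent seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


@dataclass
class SpectrumScenario:
    """Ground truth for one pair of Doppler detector channels.

    ``f_base`` places the lower channel's cutoff; the upper channel sits at
    ``f_base`` plus the Doppler difference implied by ``vmax_true``.
    ``edge_sigma_bins`` blurs the spectral edge by jittering tone frequencies
    (standard deviation in units of spectral bins).  ``snr`` is the
    signal-to-noise power ratio.  ``beam_sigma_fraction`` is the Gaussian
    beam half-width as a fraction of the capillary radius, used only by the
    centre-weighted (capillary) mode.
    """

    vmax_true: float  # mm/s
    f_base: float = 1000.0  # Hz, lower channel cutoff
    snr: float = 20.0
    edge_sigma_bins: float = 0.0
    intensity_profile: str = "uniform"  # "uniform" | "center_weighted"
    seed: int = 0
    n_tones: int = DEFAULT_N_TONES
    beam_sigma_fraction: float = 2.0

    def __post_init__(self) -> None:
        if self.vmax_true < 0:
            raise InvalidScenarioError("vmax_true must be non-negative")
        if self.snr <= 0:
            raise InvalidScenarioError("snr must be positive")
        if self.intensity_profile not in ("uniform", "center_weighted"):
            raise InvalidScenarioError(
                f"unknown intensity_profile {self.intensity_profile!r}"
            )
        if self.f_base <= 0:
            raise InvalidScenarioError("f_base must be positive")

    def channel_cutoffs(self, config: OpticalConfig) -> tuple[float, float]:
        """(f_cut_A, f_cut_B) in Hz for the upper and lower channel."""
        delta_f = invert_vmax_to_delta_f(self.vmax_true * 1e-3, config)
        return self.f_base + delta_f, self.f_base


def _tone_channel(
    rng: np.random.Generator,
    f_cut: float,
    scenario: SpectrumScenario,
    config: OpticalConfig,
    n_samples: int,
) -> np.ndarray:
    """One channel: M random-phase tones, uniform frequency law on [0, f_cut].

    Tone frequencies are quantised to the spectral grid of the acquisition
    window (one bin = ``1/doppler_window`` Hz, i.e. the finest frequency the
    window can resolve), which lets the record be synthesised exactly with
    one inverse FFT instead of summing M cosines.
    """
    M = scenario.n_tones
    freqs = rng.uniform(0.0, f_cut, size=M)
    if scenario.edge_sigma_bins > 0:
        freqs = freqs + rng.normal(
            0.0, scenario.edge_sigma_bins * config.bin_width, size=M
        )
        freqs = np.clip(freqs, 0.0, None)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=M)
    if scenario.intensity_profile == "center_weighted":
        # Poiseuille maps radius to frequency: r^2/R^2 = 1 - f/f_cut.  A
        # Gaussian beam centred on the axis weights slow (peripheral)
        # scatterers down and the near-cutoff ones up.
        r2_over_R2 = np.clip(1.0 - freqs / f_cut, 0.0, 1.0)
        amps = np.exp(-r2_over_R2 / (4.0 * scenario.beam_sigma_fraction**2))
        # keep total tone power equal to that of M unit tones
        amps *= np.sqrt(M / np.sum(amps**2))
    else:
        amps = np.ones(M)
    # quantise to the DFT grid and synthesise via the inverse transform:
    # x[k] = sum_m a_m cos(2 pi j_m k / N + phi_m)
    bin_hz = config.sampling_rate / n_samples
    j = np.clip(np.rint(freqs / bin_hz).astype(int), 0, n_samples // 2)
    X = np.zeros(n_samples // 2 + 1, dtype=complex)
    np.add.at(X, j, amps * np.exp(1j * phases) * (n_samples / 2.0))
    signal = np.fft.irfft(X, n=n_samples)
    # pin the realised signal power to the tone-power target: the same total
    # scattered intensity reaches the detector whatever the velocity, so the
    # area under the spectrum is constant by construction
    target_power = np.sum(amps**2) / 2.0
    realised = signal.var()
    if realised > 0:
        signal *= np.sqrt(target_power / realised)
    noise_sd = np.sqrt(target_power / scenario.snr)
    return signal + rng.normal(0.0, noise_sd, size=n_samples)


def draw_tone_frequencies(
    scenario: SpectrumScenario,
    f_cut: float,
    config: OpticalConfig | None = None,
) -> np.ndarray:
    """Tone frequencies (Hz, before grid quantisation) the simulator would draw.

    Exposes the frequency law — uniform on ``[0, f_cut]``, optionally edge
    jittered — for distributional checks.
    """
    if config is None:
        config = OpticalConfig()
    rng = np.random.default_rng(scenario.seed)
    freqs = rng.uniform(0.0, f_cut, size=scenario.n_tones)
    if scenario.edge_sigma_bins > 0:
        freqs = np.clip(
            freqs
            + rng.normal(0.0, scenario.edge_sigma_bins * config.bin_width, size=scenario.n_tones),
            0.0,
            None,
        )
    return freqs


def simulate_detector_record(
    scenario: SpectrumScenario, config: OpticalConfig | None = None, frame_index: int = 0
) -> DetectorRecord:
    """Two-channel detector time series for a prescribed ground-truth vmax.

    One Doppler window (30 ms at 120 kHz by default).  A zero-velocity
    scenario produces pure noise on both channels (no Doppler signal).
    """
    if config is None:
        config = OpticalConfig()
    n = config.window_samples
    rng = np.random.default_rng(scenario.seed)
    if scenario.vmax_true == 0:
        noise_sd = np.sqrt((scenario.n_tones / 2.0) / scenario.snr)
        a = rng.normal(0.0, noise_sd, size=n)
        b = rng.normal(0.0, noise_sd, size=n)
    else:
        f_a, f_b = scenario.channel_cutoffs(config)
        if max(f_a, f_b) >= config.nyquist:
            raise InvalidScenarioError(
                f"channel cutoff {max(f_a, f_b):.0f} Hz reaches the Nyquist band "
                f"({config.nyquist:.0f} Hz)"
            )
        a = _tone_channel(rng, f_a, scenario, config, n)
        b = _tone_channel(rng, f_b, scenario, config, n)
    return DetectorRecord(
        channel_a=a, channel_b=b, sampling_rate=config.sampling_rate, frame_index=frame_index
    )


def simulate_capillary_spectrum(
    scenario: SpectrumScenario, config: OpticalConfig | None = None, frame_index: int = 0
) -> tuple[PowerSpectrum, PowerSpectrum]:
    """In-vitro capillary spectra: centre-weighted tones, constant total power.

    The returned pair reproduces the characteristic enhancement just below
    the cutoff (bright beam centre = fastest scatterers) while the area under
    the spectrum stays independent of the velocity.
    """
    if config is None:
        config = OpticalConfig()
    if scenario.intensity_profile != "center_weighted":
        scenario = SpectrumScenario(
            **{**scenario.__dict__, "intensity_profile": "center_weighted"}
        )
    record = simulate_detector_record(scenario, config, frame_index=frame_index)
    return compute_power_spectrum(record, config)


@dataclass
class ImageScenario:
    """Ground truth for one fundus phantom frame.

    ``illumination_coeffs`` are the six quadratic-surface coefficients
    (1, r, c, r^2, rc, c^2) on coordinates normalised to [-1, 1];
    ``spot_offset_px`` displaces the probing-beam spot perpendicular to the
    vessel centreline.  Intensity units are 16-bit counts.
    """

    diameter_px: float
    orientation_deg: float = 0.0
    spot_offset_px: float = 0.0
    illumination_coeffs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0
    image_shape: tuple = (1040, 1392)
    background: float = 20000.0
    vessel_depth: float = 8000.0
    spot_amplitude: float = 40000.0
    edge_sigma_px: float = 3.0

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise InvalidScenarioError("diameter_px must be positive")
        h, w = self.image_shape
        if h > 1040 or w > 1392:
            raise InvalidScenarioError("image must fit the 1392x1040 sensor")
        if min(h, w) < 360:
            raise InvalidScenarioError("image must be at least 360x360 px")
        if self.diameter_px > min(h, w) / 2 or abs(self.spot_offset_px) > min(h, w) / 2 - 60:
            raise InvalidScenarioError("vessel band or spot falls outside the frame")


def simulate_fundus_image(scenario: ImageScenario) -> FundusImage:
    """Render one 16-bit fundus phantom with known diameter and orientation.

    The vessel runs through the image centre; its cross-section is a dark bar
    of the nominal width with Gaussian-smoothed edges (difference of Gaussian
    CDFs), so the half-depth points sit exactly at the nominal edges.
    """
    h, w = scenario.image_shape
    rng = np.random.default_rng(scenario.seed)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    rn = (rows - (h - 1) / 2) / ((h - 1) / 2)
    cn = (cols - (w - 1) / 2) / ((w - 1) / 2)
    a0, a1, a2, a3, a4, a5 = scenario.illumination_coeffs
    img = (
        scenario.background
        + a0 + a1 * rn + a2 * cn + a3 * rn**2 + a4 * rn * cn + a5 * cn**2
    )

    theta = np.deg2rad(scenario.orientation_deg)
    nvec = np.array([-np.sin(theta), np.cos(theta)])
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    u = (rows - center[0]) * nvec[0] + (cols - center[1]) * nvec[1]
    half = scenario.diameter_px / 2.0
    s = scenario.edge_sigma_px
    band = ndtr((u + half) / s) - ndtr((u - half) / s)
    img -= scenario.vessel_depth * band

    spot_center = center + scenario.spot_offset_px * nvec
    dist2 = (rows - spot_center[0]) ** 2 + (cols - spot_center[1]) ** 2
    spot_sigma = SPOT_FWHM_PX * _FWHM_TO_SIGMA
    img += scenario.spot_amplitude * np.exp(-dist2 / (2.0 * spot_sigma**2))

    if scenario.noise_sigma > 0:
        img += rng.normal(0.0, scenario.noise_sigma, size=img.shape)
    return FundusImage(
        pixels=np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    )


@dataclass
class BifurcationScenario:
    """Ground-truth vessel states at one venous junction."""

    parent: tuple  # (diameter_um, vmax_mm_s)
    daughters: tuple  # ((d1_um, v1_mm_s), (d2_um, v2_mm_s))
    conserved: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parent[0] <= 0 or any(d[0] <= 0 for d in self.daughters):
            raise InvalidScenarioError("diameters must be positive")
        if self.parent[1] < 0 or any(d[1] < 0 for d in self.daughters):
            raise InvalidScenarioError("velocities must be non-negative")
        if self.conserved:
            fp = compute_flow(*self.parent)
            fd = sum(compute_flow(*d) for d in self.daughters)
            if abs(fp - fd) > 1e-9 * fp:
                raise InvalidScenarioError(
                    "scenario marked conserved but parent and daughter flows differ"
                )

    @property
    def flows_ul_min(self) -> tuple[float, float, float]:
        return (
            compute_flow(*self.parent),
            compute_flow(*self.daughters[0]),
            compute_flow(*self.daughters[1]),
        )


def make_conserved_bifurcation(
    parent_diameter_um: float,
    parent_vmax_mm_s: float,
    daughter_diameters_um: tuple[float, float],
    split_fraction: float = 0.5,
    seed: int = 0,
) -> BifurcationScenario:
    """Build an exactly conserved junction by solving the daughter velocities.

    ``split_fraction`` of the parent flow goes to the first daughter; both
    daughter velocities follow from their chosen diameters.
    """
    if not 0.0 < split_fraction < 1.0:
        raise InvalidScenarioError("split_fraction must be in (0, 1)")
    f_parent = compute_flow(parent_diameter_um, parent_vmax_mm_s)
    d1, d2 = daughter_diameters_um
    v1 = flow_to_vmax(split_fraction * f_parent, d1)
    v2 = flow_to_vmax((1.0 - split_fraction) * f_parent, d2)
    return BifurcationScenario(
        parent=(parent_diameter_um, parent_vmax_mm_s),
        daughters=((d1, v1), (d2, v2)),
        conserved=True,
        seed=seed,
    )


@dataclass
class VesselAcquisition:
    """Frames of one simulated vessel plus its ground truth."""

    truth_diameter_um: float
    truth_vmax_mm_s: float
    frames: list  # list of (FundusImage, DetectorRecord)


def simulate_bifurcation(
    scenario: BifurcationScenario,
    config: OpticalConfig | None = None,
    snr: float = 20.0,
    image_shape: tuple = (1040, 1392),
    image_snr: float = 20.0,
    axial_length_mm: float | None = None,
) -> dict[str, VesselAcquisition]:
    """Paired (image, detector-record) frames for parent and daughter vessels.

    Each vessel gets ``config.frames_per_acquisition`` frames.  Image noise
    is set so the vessel contrast-to-noise ratio equals ``image_snr``; the
    Doppler SNR is ``snr``.  Vessel orientations are drawn from the template
    angle grid; the spot sits a few pixels off each centreline.
    """
    if config is None:
        config = OpticalConfig()
    if axial_length_mm is None:
        axial_length_mm = config.axial_length_assumed
    vessels = {
        "PV": scenario.parent,
        "DV1": scenario.daughters[0],
        "DV2": scenario.daughters[1],
    }
    rng = np.random.default_rng(scenario.seed)
    seeds = _child_seeds(scenario.seed, 2 * 3 * config.frames_per_acquisition)
    out: dict[str, VesselAcquisition] = {}
    it = iter(seeds)
    for name, (d_um, vmax) in vessels.items():
        d_px = um_to_pixels(d_um, axial_length_mm, config)
        if vmax * 1e-3 <= 0:
            raise InvalidScenarioError(f"vessel {name}: non-positive velocity")
        orientation = float(rng.choice(np.arange(0.0, 180.0, 15.0)))
        frames = []
        for k in range(config.frames_per_acquisition):
            img = simulate_fundus_image(
                ImageScenario(
                    diameter_px=d_px,
                    orientation_deg=orientation,
                    spot_offset_px=5.0,
                    noise_sigma=8000.0 / image_snr,
                    seed=next(it),
                    image_shape=image_shape,
                )
            )
            img.frame_index = k
            rec = simulate_detector_record(
                SpectrumScenario(vmax_true=vmax, snr=snr, seed=next(it)),
                config,
                frame_index=k,
            )
            frames.append((img, rec))
        out[name] = VesselAcquisition(
            truth_diameter_um=d_um, truth_vmax_mm_s=vmax, frames=frames
        )
    return out
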
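"""Maximum-Doppler-shift (cutoff) estimation from step-shaped power spectra.

Laminar flow with a parabolic velocity profile and uniformly distributed
scatterers produces a flat Doppler spectrum up to a sharp edge at the shift of
the fastest scatterers.  The cutoff is located on the normalised cumulative
spectrum ``rc`` (non-decreasing, ending at 1), which rises linearly over the
flow band and is flat beyond it:

1. fit a "plateau" line to ``rc`` over the last third of the bins, where only
   noise is expected;
2. find ``kx``, the largest bin whose ``rc`` value lies at least 10 % below
   the local plateau-line value;
3. fit a "rise" line to ``rc`` over bins 1..kx;
4. the abscissa of the intersection of the two lines, converted to Hz, is the
   cutoff.

Spectra without a resolvable step (flat, noise-only, or with near-parallel
fitted lines) are flagged ``no_cutoff``; intersections outside (0, Nyquist]
are flagged ``out_of_band``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NoMeasurementError
from .spectra import PowerSpectrum

__all__ = ["CutoffResult", "cumulative_rc", "detect_cutoff", "delta_cutoff"]

#: rise slope must exceed the plateau slope by this factor, else ``no_cutoff``
DEFAULT_SLOPE_FACTOR = 5.0

#: relative drop below the plateau line that defines the end of the rise region
PLATEAU_DROP_FRACTION = 0.10


@dataclass
class CutoffResult:
    """Estimated maximum frequency shift with two-line fit diagnostics.

    Line parameters live in (1-based bin index, rc) space; ``cutoff_hz`` is
    the intersection abscissa mapped onto the spectrum's frequency axis.
    """

    cutoff_hz: float
    kx: int
    rise_slope: float
    rise_intercept: float
    plateau_slope: float
    plateau_intercept: float
    quality_flag: str  # "ok" | "no_cutoff" | "out_of_band"
    channel_label: str = "A"
    frame_index: int = 0

    @property
    def ok(self) -> bool:
        return self.quality_flag == "ok"


def cumulative_rc(spectrum: PowerSpectrum) -> np.ndarray:
    """Normalised cumulative power: ``rc(i) = sum(s[1..i]) / sum(s[1..N])``.

    Non-decreasing, scale-invariant, ends at exactly 1.  An all-zero spectrum
    has no cumulative shape and raises :class:`InvalidInputError`.
    """
    total = spectrum.power.sum()
    if total <= 0:
        raise InvalidInputError("all-zero spectrum has no cutoff")
    return np.cumsum(spectrum.power) / total


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Unweighted least-squares slope and intercept."""
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def detect_cutoff(
    spectrum: PowerSpectrum, slope_factor: float = DEFAULT_SLOPE_FACTOR
) -> CutoffResult:
    """Locate the spectral step edge by the two-line-intersection procedure."""
    N = spectrum.power.size
    meta = dict(channel_label=spectrum.channel_label, frame_index=spectrum.frame_index)

    def flagged(flag: str, **kw) -> CutoffResult:
        defaults = dict(
            cutoff_hz=float("nan"),
            kx=0,
            rise_slope=float("nan"),
            rise_intercept=float("nan"),
            plateau_slope=float("nan"),
            plateau_intercept=float("nan"),
        )
        defaults.update(kw)
        return CutoffResult(quality_flag=flag, **defaults, **meta)

    if spectrum.power.sum() <= 0:
        return flagged("no_cutoff")
    rc = cumulative_rc(spectrum)
    bins = np.arange(1, N + 1, dtype=float)  # 1-based bin indices

    # plateau: least-squares line over the last third of the bins
    start = int(np.ceil(2 * N / 3))  # 1-based first plateau bin
    p_slope, p_icpt = _ols_line(bins[start - 1 :], rc[start - 1 :])
    plateau_line = p_slope * bins + p_icpt

    # kx: largest bin at least 10 % below the local plateau-line value
    # tolerance absorbs float round-off when rc sits exactly on the 10% level
    tol = 1e-9 * np.maximum(np.abs(plateau_line), 1.0)
    below = plateau_line - rc >= PLATEAU_DROP_FRACTION * plateau_line - tol
    qualifying = np.nonzero(below)[0]
    if qualifying.size == 0 or qualifying[-1] + 1 < 2:
        return flagged("no_cutoff", plateau_slope=p_slope, plateau_intercept=p_icpt)
    kx = int(qualifying[-1] + 1)  # back to 1-based

    r_slope, r_icpt = _ols_line(bins[:kx], rc[:kx])

    diag = dict(
        kx=kx,
        rise_slope=r_slope,
        rise_intercept=r_icpt,
        plateau_slope=p_slope,
        plateau_intercept=p_icpt,
    )

    # near-parallel lines (flat or noise-only spectra) carry no step
    if r_slope <= 0 or r_slope <= slope_factor * max(p_slope, 0.0):
        return flagged("no_cutoff", **diag)

    bin_cross = (p_icpt - r_icpt) / (r_slope - p_slope)
    cutoff_hz = float(spectrum.frequencies[0] + (bin_cross - 1.0) * spectrum.bin_width)
    if not (0.0 < cutoff_hz <= spectrum.nyquist):
        return flagged("out_of_band", **diag)
    return CutoffResult(cutoff_hz=cutoff_hz, quality_flag="ok", **diag, **meta)


def delta_cutoff(result_a: CutoffResult, result_b: CutoffResult) -> float:
    """Absolute cutoff-frequency difference ``|fA - fB|`` in Hz.

    Both results must have passed quality control; otherwise the frame
    carries no velocity measurement.
    """
    if not (result_a.ok and result_b.ok):
        bad = [
            f"channel {r.channel_label}: {r.quality_flag}"
            for r in (result_a, result_b)
            if not r.ok
        ]
        raise NoMeasurementError("; ".join(bad))
    return abs(result_a.cutoff_hz - result_b.cutoff_hz)
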
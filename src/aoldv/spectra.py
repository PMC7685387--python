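"""Two-channel detector records and Doppler power spectra.

Each 100 ms acquisition frame carries one 30 ms window of the two detector
signals, sampled at 120 kHz.  A single rectangular-window periodogram per
window (no averaging) yields one power spectrum per channel; an optional Hann
window is available for noise-robustness experiments.  DC is removed by mean
subtraction before the transform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import OpticalConfig
from .errors import InvalidInputError

__all__ = [
    "DetectorRecord",
    "PowerSpectrum",
    "compute_power_spectrum",
    "write_record_csv",
    "read_record_csv",
    "write_spectra_csv",
    "read_spectra_csv",
]


@dataclass
class DetectorRecord:
    """One frame of the two-channel detector time series."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    sampling_rate: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.channel_a.shape != self.channel_b.shape or self.channel_a.ndim != 1:
            raise InvalidInputError("channels must be 1-D and of equal length")
        if self.channel_a.size < 2:
            raise InvalidInputError("record needs at least 2 samples")
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")


@dataclass
class PowerSpectrum:
    """One-sided Doppler power spectrum of a single channel.

    ``power[k]`` is the spectral power in the bin centred at
    ``frequencies[k]``; bins are uniformly spaced and ascending, bounded by
    the Nyquist frequency.
    """

    frequencies: np.ndarray
    power: np.ndarray
    channel_label: str = "A"
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape or self.frequencies.ndim != 1:
            raise InvalidInputError("frequencies and power must be 1-D, same length")
        if self.frequencies.size < 8:
            raise InvalidInputError("spectrum needs at least 8 bins")
        if np.any(self.power < 0):
            raise InvalidInputError("power must be non-negative")
        if self.frequencies[0] < 0:
            raise InvalidInputError("frequencies must be non-negative")
        df = np.diff(self.frequencies)
        if np.any(df <= 0) or not np.allclose(df, df[0], rtol=1e-6):
            raise InvalidInputError("frequencies must ascend with uniform spacing")

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])


def compute_power_spectrum(
    record: DetectorRecord,
    config: OpticalConfig | None = None,
    window: str = "rectangular",
) -> tuple[PowerSpectrum, PowerSpectrum]:
    """Periodogram of one Doppler window for each channel.

    The channel mean is subtracted before the transform (so the DC bin is
    ~zero), and the one-sided power is scaled so that its sum equals the
    time-domain variance of the de-meaned, windowed signal (Parseval).

    If ``config`` is given, exactly one Doppler window
    (``config.window_samples`` samples) is taken from the start of the record;
    a shorter record is an error.  Without a config the whole record is one
    window.
    """
    if config is not None:
        n = config.window_samples
        if record.channel_a.size < n:
            raise InvalidInputError(
                f"record has {record.channel_a.size} samples; one Doppler window "
                f"needs {n}"
            )
    else:
        n = record.channel_a.size

    if window == "rectangular":
        taper = np.ones(n)
    elif window == "hann":
        taper = np.hanning(n)
    else:
        raise InvalidInputError(f"unknown window {window!r}")

    freqs = np.fft.rfftfreq(n, d=1.0 / record.sampling_rate)
    out = []
    for label, samples in (("A", record.channel_a), ("B", record.channel_b)):
        x = samples[:n]
        x = (x - x.mean()) * taper
        X = np.fft.rfft(x)
        power = np.abs(X) ** 2 / n**2
        # fold negative frequencies into the positive half (one-sided)
        power[1:] *= 2.0
        if n % 2 == 0:
            power[-1] /= 2.0  # Nyquist bin is not duplicated
        out.append(
            PowerSpectrum(freqs, power, channel_label=label, frame_index=record.frame_index)
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# CSV interchange


def write_record_csv(path: str | Path, record: DetectorRecord) -> None:
    """Write a two-channel time series with a sampling-rate header comment."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={record.sampling_rate:g}\n")
        fh.write(f"# frame_index={record.frame_index}\n")
        pd.DataFrame(
            {"channel_a": record.channel_a, "channel_b": record.channel_b}
        ).to_csv(fh, index=False)


def read_record_csv(path: str | Path) -> DetectorRecord:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            m = re.match(r"#\s*(\w+)=([-\w.+e]+)", line)
            if m:
                meta[m.group(1)] = m.group(2)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if "sampling_rate_hz" not in meta:
        raise InvalidInputError(f"{path}: missing '# sampling_rate_hz=' header")
    return DetectorRecord(
        channel_a=df["channel_a"].to_numpy(),
        channel_b=df["channel_b"].to_numpy(),
        sampling_rate=float(meta["sampling_rate_hz"]),
        frame_index=int(meta.get("frame_index", 0)),
    )


def write_spectra_csv(
    path: str | Path, pairs: list[tuple[PowerSpectrum, PowerSpectrum]]
) -> None:
    """Write paired channel-A/B spectra as frequency_hz,power_a,power_b,frame_index."""
    frames = []
    for sa, sb in pairs:
        if not np.array_equal(sa.frequencies, sb.frequencies):
            raise InvalidInputError("paired spectra must share a frequency axis")
        frames.append(
            pd.DataFrame(
                {
                    "frequency_hz": sa.frequencies,
                    "power_a": sa.power,
                    "power_b": sb.power,
                    "frame_index": sa.frame_index,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> list[tuple[PowerSpectrum, PowerSpectrum]]:
    df = pd.read_csv(path)
    required = {"frequency_hz", "power_a", "power_b", "frame_index"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"{path}: columns must include {sorted(required)}")
    pairs = []
    for idx, grp in df.groupby("frame_index", sort=True):
        f = grp["frequency_hz"].to_numpy()
        pairs.append(
            (
                PowerSpectrum(f, grp["power_a"].to_numpy(), "A", int(idx)),
                PowerSpectrum(f, grp["power_b"].to_numpy(), "B", int(idx)),
            )
        )
    return pairs
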
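"""Vessel lumen diameter near the probing-beam spot on AO fundus images.

The probing-beam spot marks where the Doppler measurement is taken, so the
diameter is measured right there.  The pipeline, applied to one 16-bit
grayscale frame (canonically 1040 x 1392 px):

1.  detect the spot: threshold at 80 % of the maximal intensity, keep the
    largest 8-connected component, intensity-weighted centroid;
2.  cut a 360 x 360 px region of interest (ROI) around the centroid, shifted
    inward at image borders;
3.  remove low-frequency illumination: least-squares fit of a second-order
    polynomial surface, work on the residual;
4.  find the rough vessel orientation and centreline offset by normalised
    cross-correlation with 24 synthetic dark-bar templates (15 degree
    increments; bars are 180-degree symmetric so 12 distinct orientations);
5.  extract intensity profiles perpendicular to the centreline every 2 px;
6.  per profile, measure the distance between the vessel edges at half the
    trough depth;
7.  discard aberrant widths (outside mean +/- 3 sd) and average the rest;
8.  convert pixels to micrometres with the camera calibration
    ``d_um = n_px * 19.269 * (L - 1.82) / 373.87`` at axial length L mm.

Vessels are dark bands on a bright background (absorption); the trough sign
is fixed.  QC failures raise :class:`SpotNotFoundError`,
:class:`VesselNotFoundError` or :class:`DiameterNotMeasurableError`, which
frame-level pipelines map to an excluded frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import OpticalConfig
from .errors import AoldvError, InvalidInputError

__all__ = [
    "FundusImage",
    "SpotDetection",
    "VesselFit",
    "DiameterEstimate",
    "QCError",
    "SpotNotFoundError",
    "VesselNotFoundError",
    "DiameterNotMeasurableError",
    "detect_spot",
    "extract_roi",
    "flatten_background",
    "estimate_orientation",
    "extract_profiles",
    "measure_edge_distance",
    "reject_aberrant",
    "pixels_to_um",
    "um_to_pixels",
    "measure_diameter",
    "read_fundus_image",
    "write_fundus_image",
    "TEMPLATE_ANGLES_DEG",
]

ROI_SIZE = 360
PROFILE_LENGTH = 180
PROFILE_SPACING = 2.0
TEMPLATE_BAR_WIDTH = 60.0  # px, mid-range retinal vein under the calibration
TEMPLATE_SMOOTH_SIGMA = 3.0  # px
TEMPLATE_OFFSET_RANGE = 60  # px, perpendicular search around the spot centroid
#: 24 dark-bar templates, 15 degree increments; orientation is reported mod 180
TEMPLATE_ANGLES_DEG = tuple(15.0 * k for k in range(24))
CORRELATION_FLOOR = 0.2
BASELINE_PERCENTILE = 85.0
SPOT_MAX_AREA_FRACTION = 0.2  # a "spot" covering more than this is no spot


class QCError(AoldvError):
    """A frame failed image quality control (excluded, not fatal)."""


class SpotNotFoundError(QCError):
    pass


class VesselNotFoundError(QCError):
    pass


class DiameterNotMeasurableError(QCError):
    pass


@dataclass
class FundusImage:
    """One 16-bit grayscale AO fundus frame."""

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InvalidInputError("fundus image must be 2-D")
        if self.pixels.shape[0] < ROI_SIZE or self.pixels.shape[1] < ROI_SIZE:
            raise InvalidInputError(
                f"fundus image must be at least {ROI_SIZE}x{ROI_SIZE} px"
            )
        if self.pixels.min() < 0 or self.pixels.max() > 65535:
            raise InvalidInputError("intensities must lie in [0, 65535]")


@dataclass
class SpotDetection:
    """Probing-beam spot: boolean mask and sub-pixel centroid."""

    centroid_row: float
    centroid_col: float
    mask: np.ndarray


@dataclass
class VesselFit:
    """Per-profile evidence behind one diameter estimate."""

    orientation_deg: float  # [0, 180), counterclockwise from the row axis
    centerline_offset_px: float  # signed perpendicular offset from spot centroid
    profile_positions: np.ndarray  # px along the centreline
    edge_distances_px: np.ndarray  # per usable profile
    aberrant_flags: np.ndarray  # True where outside mean +/- 3 sd
    diameter_px: float  # mean of non-aberrant widths
    peak_correlation: float = float("nan")


@dataclass
class DiameterEstimate:
    diameter_px: float
    diameter_um: float
    axial_length_mm: float
    fit: VesselFit | None = None

    @property
    def n_profiles(self) -> int:
        return 0 if self.fit is None else int(self.fit.edge_distances_px.size)

    @property
    def n_rejected(self) -> int:
        return 0 if self.fit is None else int(self.fit.aberrant_flags.sum())


# ---------------------------------------------------------------------------
# pipeline steps


def detect_spot(image: FundusImage) -> SpotDetection:
    """Largest 8-connected component above 80 % of the maximal intensity."""
    px = np.asarray(image.pixels, dtype=float)
    vmax = px.max()
    if vmax <= 0:
        raise SpotNotFoundError("image has no positive intensity")
    mask = px >= 0.8 * vmax
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise SpotNotFoundError("no pixels above the 80% threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    spot_mask = labels == best
    if spot_mask.mean() > SPOT_MAX_AREA_FRACTION:
        raise SpotNotFoundError(
            "brightest component covers most of the frame (no focal spot)"
        )
    w = px * spot_mask
    total = w.sum()
    rows, cols = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
    return SpotDetection(
        centroid_row=float((rows * w).sum() / total),
        centroid_col=float((cols * w).sum() / total),
        mask=spot_mask,
    )


def extract_roi(
    image: FundusImage, spot: SpotDetection
) -> tuple[np.ndarray, tuple[int, int]]:
    """360 x 360 window around the rounded spot centroid.

    Near a border the window is shifted inward, never shrunk.  Returns the
    window (float copy) and its (row, col) top-left corner in image
    coordinates.
    """
    h, w = image.pixels.shape
    if h < ROI_SIZE or w < ROI_SIZE:
        raise InvalidInputError("image smaller than the ROI")
    r0 = int(round(spot.centroid_row)) - ROI_SIZE // 2
    c0 = int(round(spot.centroid_col)) - ROI_SIZE // 2
    r0 = min(max(r0, 0), h - ROI_SIZE)
    c0 = min(max(c0, 0), w - ROI_SIZE)
    roi = np.asarray(
        image.pixels[r0 : r0 + ROI_SIZE, c0 : c0 + ROI_SIZE], dtype=float
    ).copy()
    return roi, (r0, c0)


def flatten_background(roi: np.ndarray, exclude: np.ndarray | None = None) -> np.ndarray:
    """Subtract a least-squares second-order polynomial surface from the ROI.

    Models low-frequency illumination variation; the residual carries the
    vessel band and the spot.  Pixels flagged in ``exclude`` (e.g. the
    probing-beam spot, a known instrument artifact rather than illumination)
    are left out of the fit but still flattened.
    """
    roi = np.asarray(roi, dtype=float)
    h, w = roi.shape
    # normalised coordinates for a well-conditioned design matrix
    r = (np.arange(h) - (h - 1) / 2) / max(h - 1, 1)
    c = (np.arange(w) - (w - 1) / 2) / max(w - 1, 1)
    R, C = np.meshgrid(r, c, indexing="ij")
    A = np.stack(
        [np.ones_like(R), R, C, R * R, R * C, C * C], axis=-1
    ).reshape(-1, 6)
    if exclude is None:
        keep = slice(None)
    else:
        keep = ~np.asarray(exclude, dtype=bool).ravel()
    coef, *_ = np.linalg.lstsq(A[keep], roi.ravel()[keep], rcond=None)
    return roi - (A @ coef).reshape(h, w)


def _bar_template(u: np.ndarray) -> np.ndarray:
    """Dark-bar template value at perpendicular distance ``u`` (px).

    A bar of width :data:`TEMPLATE_BAR_WIDTH` and depth -1, smoothed with a
    Gaussian of :data:`TEMPLATE_SMOOTH_SIGMA` px: the difference of two
    Gaussian CDFs.
    """
    from scipy.special import ndtr

    half = TEMPLATE_BAR_WIDTH / 2.0
    s = TEMPLATE_SMOOTH_SIGMA
    return -(ndtr((u + half) / s) - ndtr((u - half) / s))


def estimate_orientation(
    residual: np.ndarray,
    center: tuple[float, float],
    correlation_floor: float = CORRELATION_FLOOR,
    spot_exclusion_radius_px: float = 1.5 * 31.0,
) -> tuple[float, float, float]:
    """Rough vessel orientation and centreline offset by template matching.

    Correlates the background-flattened ROI with synthetic dark-bar templates
    over the 15-degree angle grid and perpendicular offsets within
    +/-60 px of ``center`` (the spot centroid in ROI coordinates).  Because a
    bar is symmetric under 180-degree rotation the 24 template angles reduce
    to 12 distinct correlations; the winning orientation is reported in
    [0, 180).

    Returns ``(orientation_deg, centerline_offset_px, peak_correlation)``.
    """
    res = np.asarray(residual, dtype=float)
    h, w = res.shape
    rows, cols = np.mgrid[0:h, 0:w]
    dr = (rows - center[0]).astype(float)
    dc = (cols - center[1]).astype(float)
    # the probing-beam spot outshines the vessel locally; keep it out of the
    # correlation so it cannot repel the dark-bar template
    keep = (dr**2 + dc**2) > spot_exclusion_radius_px**2
    res_k = res[keep]
    dr = dr[keep]
    dc = dc[keep]
    n_pix = res_k.size
    mean_r = res_k.mean()
    var_r = res_k.var()
    if var_r <= 0:
        raise VesselNotFoundError("flat residual: nothing to correlate with")

    offsets = np.arange(-TEMPLATE_OFFSET_RANGE, TEMPLATE_OFFSET_RANGE + 1, dtype=float)
    best = (-np.inf, 0.0, 0.0)
    for theta_deg in TEMPLATE_ANGLES_DEG:
        if theta_deg >= 180.0:
            continue  # bar templates are 180-degree symmetric
        theta = np.deg2rad(theta_deg)
        # signed perpendicular distance to the line through `center` at theta
        u = -np.sin(theta) * dr + np.cos(theta) * dc
        ui = np.rint(u).astype(int)
        shift = -ui.min()
        cnt = np.bincount(ui + shift)
        sum_res = np.bincount(ui + shift, weights=res_k)
        u_axis = np.arange(cnt.size, dtype=float) - shift
        # template support is compact: evaluate once per offset on the u axis
        for o in offsets:
            b = _bar_template(u_axis - o)
            sum_t = cnt @ b
            sum_t2 = cnt @ (b * b)
            sum_rt = sum_res @ b
            mean_t = sum_t / n_pix
            var_t = sum_t2 / n_pix - mean_t**2
            if var_t <= 0:
                continue
            ncc = (sum_rt / n_pix - mean_r * mean_t) / np.sqrt(var_t * var_r)
            if ncc > best[0]:
                best = (float(ncc), theta_deg % 180.0, float(o))
    peak, orientation, offset = best
    if peak < correlation_floor:
        raise VesselNotFoundError(
            f"peak template correlation {peak:.3f} below floor {correlation_floor}"
        )
    return orientation, offset, peak


def extract_profiles(
    residual: np.ndarray,
    orientation_deg: float,
    centerline_offset_px: float,
    center: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear intensity profiles perpendicular to the vessel centreline.

    Profiles are 180 px long, sampled at 1 px steps centred on the
    centreline, one profile every 2 px along it, restricted to profiles that
    lie fully inside the ROI.  Returns ``(profiles, positions)`` with
    ``profiles`` of shape (n_profiles, 180) and ``positions`` the centreline
    coordinate of each profile in px.
    """
    res = np.asarray(residual, dtype=float)
    h, w = res.shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    theta = np.deg2rad(orientation_deg)
    d = np.array([np.cos(theta), np.sin(theta)])  # along the centreline
    n = np.array([-np.sin(theta), np.cos(theta)])  # perpendicular
    origin = np.asarray(center, dtype=float) + centerline_offset_px * n

    # perpendicular sample offsets, symmetric about the centreline
    s = np.arange(PROFILE_LENGTH, dtype=float) - (PROFILE_LENGTH - 1) / 2.0
    half_span = max(h, w)
    t = np.arange(-half_span, half_span + 1e-9, PROFILE_SPACING)

    # sample coordinates: (2, n_t, n_s)
    pts = (
        origin[:, None, None]
        + d[:, None, None] * t[None, :, None]
        + n[:, None, None] * s[None, None, :]
    )
    inside = (
        (pts[0] >= 0) & (pts[0] <= h - 1) & (pts[1] >= 0) & (pts[1] <= w - 1)
    ).all(axis=1)
    if not inside.any():
        return np.empty((0, PROFILE_LENGTH)), np.empty(0)
    t = t[inside]
    pts = pts[:, inside, :]
    profiles = ndimage.map_coordinates(
        res, pts.reshape(2, -1), order=1, mode="nearest"
    ).reshape(t.size, PROFILE_LENGTH)
    return profiles, t


def _edge_crossings(
    profile: np.ndarray,
    baseline_percentile: float = BASELINE_PERCENTILE,
    depth_floor_sigmas: float = 5.0,
) -> tuple[float, float]:
    """Sub-pixel (left, right) half-depth crossing positions of the trough."""
    p = np.asarray(profile, dtype=float)
    if p.size < 8:
        raise InvalidInputError("profile too short")
    baseline = np.percentile(p, baseline_percentile)
    i_min = int(np.argmin(p))
    depth = baseline - p[i_min]
    # robust noise from first differences; the (smoothed) edges barely register
    sigma = 1.4826 * np.median(np.abs(np.diff(p))) / np.sqrt(2.0)
    floor = max(depth_floor_sigmas * sigma, 1e-9 * max(abs(baseline), 1.0), 1e-12)
    if depth <= floor:
        raise DiameterNotMeasurableError("no trough above the noise floor")
    # a bright intrusion (probing-beam spot crossing the profile) invalidates
    # the single-trough assumption
    if p.max() - baseline >= 0.25 * depth:
        raise DiameterNotMeasurableError("bright intrusion inside the profile")
    half = baseline - depth / 2.0

    def _crossing(step: int) -> float:
        i = i_min
        while 0 <= i + step < p.size and p[i + step] < half:
            i += step
        j = i + step
        if not (0 <= j < p.size):
            # the edge leaves the window: the crossing cannot be located
            raise DiameterNotMeasurableError("vessel edge outside the profile window")
        # linear interpolation between the last sub-half and first super-half sample
        frac = (half - p[i]) / (p[j] - p[i])
        return i + step * frac

    return _crossing(-1), _crossing(+1)


def measure_edge_distance(
    profile: np.ndarray,
    baseline_percentile: float = BASELINE_PERCENTILE,
    depth_floor_sigmas: float = 5.0,
) -> float:
    """Vessel width of one cross-profile: distance between the half-depth edges.

    The baseline is a high percentile of the profile (robust to the trough
    occupying a large share of the 180 px window for wide vessels); the
    trough depth is baseline minus minimum.  The two crossings of the level
    halfway between baseline and minimum, located by linear interpolation
    around the minimum, bound the lumen.

    Raises :class:`DiameterNotMeasurableError` when no trough rises above the
    noise floor (``depth_floor_sigmas`` times a difference-based robust noise
    estimate), when a bright intrusion (the probing-beam spot) corrupts the
    profile, or when an edge leaves the profile window; such profiles are
    excluded, not fatal.
    """
    left, right = _edge_crossings(profile, baseline_percentile, depth_floor_sigmas)
    return float(right - left)


def reject_aberrant(widths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass outlier rejection: flag widths outside mean +/- 3 sample sd.

    Returns ``(kept_widths, flags)`` with ``flags[i]`` True for rejected
    entries.  Requires at least 3 widths.
    """
    w = np.asarray(widths, dtype=float)
    if w.size < 3:
        raise DiameterNotMeasurableError(
            f"only {w.size} usable profiles; need at least 3"
        )
    mean = w.mean()
    sd = w.std(ddof=1)
    flags = np.abs(w - mean) > 3.0 * sd
    return w[~flags], flags


def pixels_to_um(n_px: float, axial_length_mm: float, config: OpticalConfig) -> float:
    """Camera calibration: ``n_px * a * (L - b) / c`` micrometres.

    Uses the subject's measured axial length ``L`` (mm) — the one place the
    individual eye length enters the pipeline.
    """
    if n_px < 0:
        raise InvalidInputError("pixel count must be non-negative")
    if axial_length_mm <= config.calib_b:
        raise InvalidInputError(
            f"axial length must exceed {config.calib_b} mm for the calibration"
        )
    return n_px * config.calib_a * (axial_length_mm - config.calib_b) / config.calib_c


def um_to_pixels(d_um: float, axial_length_mm: float, config: OpticalConfig) -> float:
    """Inverse of :func:`pixels_to_um` (used to place phantom vessels)."""
    if axial_length_mm <= config.calib_b:
        raise InvalidInputError(
            f"axial length must exceed {config.calib_b} mm for the calibration"
        )
    return d_um * config.calib_c / (config.calib_a * (axial_length_mm - config.calib_b))


def measure_diameter(
    image: FundusImage,
    axial_length_mm: float | None = None,
    config: OpticalConfig | None = None,
) -> DiameterEstimate:
    """Full diameter pipeline on one frame.

    QC failures (no spot, no vessel, too few usable profiles) propagate as
    :class:`QCError` subclasses so callers can exclude the frame.
    """
    if config is None:
        config = OpticalConfig()
    if axial_length_mm is None:
        axial_length_mm = config.axial_length_assumed

    spot = detect_spot(image)
    roi, (r0, c0) = extract_roi(image, spot)
    center = (spot.centroid_row - r0, spot.centroid_col - c0)
    # keep the (dilated) spot out of the illumination fit: its tails otherwise
    # drag the polynomial up around the very region being measured
    rows, cols = np.mgrid[0:ROI_SIZE, 0:ROI_SIZE]
    spot_zone = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 < (1.5 * 31.0) ** 2
    residual = flatten_background(roi, exclude=spot_zone)
    orientation, offset, peak = estimate_orientation(residual, center)

    # the template gives only a rough centreline (its correlation is flat in
    # the offset once the bar sits inside a wider vessel); one refinement pass
    # re-centres it on the median trough midpoint of the measured profiles
    def _pass(offset_px):
        profiles, positions = extract_profiles(residual, orientation, offset_px, center)
        widths, mids, pos = [], [], []
        for prof, t in zip(profiles, positions):
            try:
                left, right = _edge_crossings(prof)
            except DiameterNotMeasurableError:
                continue
            widths.append(right - left)
            mids.append((left + right) / 2.0 - (PROFILE_LENGTH - 1) / 2.0)
            pos.append(t)
        return np.asarray(widths), np.asarray(mids), np.asarray(pos)

    widths, mids, kept_pos = _pass(offset)
    if widths.size >= 3:
        decentre = float(np.median(mids))
        if abs(decentre) > 2.0:
            offset += decentre
            widths, mids, kept_pos = _pass(offset)
    kept, flags = reject_aberrant(widths)
    diameter_px = float(kept.mean())
    fit = VesselFit(
        orientation_deg=orientation,
        centerline_offset_px=offset,
        profile_positions=np.asarray(kept_pos),
        edge_distances_px=widths,
        aberrant_flags=flags,
        diameter_px=diameter_px,
        peak_correlation=peak,
    )
    return DiameterEstimate(
        diameter_px=diameter_px,
        diameter_um=pixels_to_um(diameter_px, axial_length_mm, config),
        axial_length_mm=axial_length_mm,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# image I/O


def read_fundus_image(path: str | Path, frame_index: int = 0) -> FundusImage:
    """Read a 16-bit grayscale TIFF or PNG fundus frame."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        px = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        px = iio.imread(path)
    if px.ndim == 3:  # tolerate single-channel images stored with an axis
        px = px.squeeze()
    return FundusImage(pixels=px, frame_index=frame_index)


def write_fundus_image(path: str | Path, image: FundusImage) -> None:
    path = Path(path)
    px = np.asarray(image.pixels, dtype=np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, px)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, px)
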
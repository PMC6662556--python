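"""Gel densitometry: from a grayscale gel image to calibrated telomere-length distributions.

A telomere restriction fragment (TRF) assay separates digested genomic DNA by
size on a gel; a telomere-specific probe makes the telomeric fragments visible
as a smear in each sample lane.  Because one probe molecule anneals to one
telomere molecule, the optical density (OD) at a row of the lane is
proportional to the number of telomere molecules whose fragment size migrates
to that row.  This module converts pixel intensities into per-individual
distributions of fragment size (kb) weighted by molecule count:

1. ``extract_lane_profile`` averages pixel intensity across the lane width to
   get an OD trace down the lane.
2. ``detect_ladder_peaks`` finds the band positions of a molecular-weight
   ladder lane.
3. ``fit_ladder_calibration`` fits a cubic polynomial mapping pixel row to
   fragment size (kb), valid between the outermost visible size markers
   (1.636-40 kb by default).
4. ``estimate_background`` reads the background level from a horizontal line
   placed just below the lowest size marker.
5. ``profile_to_distribution`` applies calibration, background subtraction and
   the analysis window to produce a :class:`TLDistribution`.

Image rows are 0-based with row 0 at the top (nearest the wells, largest
fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

#: Analysis window between the two outermost visible size markers (kb).
DEFAULT_WINDOW_KB: tuple[float, float] = (1.636, 40.0)


@dataclass
class GelImage:
    """A rectangular non-negative grayscale intensity grid."""

    pixels: np.ndarray
    bit_depth: int = 16
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("gel image must be a 2-D grayscale array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("gel image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("gel image contains negative intensities")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class LaneSpec:
    """Position and role of one lane on a gel.

    ``kind`` is ``sample`` for individuals, ``ladder`` for molecular-weight
    ladders and ``standard`` for the repeated quality-control samples run on
    every gel.
    """

    lane_id: str
    center_col_px: int
    width_px: int
    kind: str = "sample"
    gel_id: str = ""

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ValueError(f"lane {self.lane_id}: width must be >= 1 px")
        if self.kind not in ("sample", "ladder", "standard"):
            raise ValueError(f"lane {self.lane_id}: unknown kind {self.kind!r}")

    def columns(self) -> tuple[int, int]:
        """Half-open column range covered by the lane."""
        half = self.width_px // 2
        lo = self.center_col_px - half
        return lo, lo + self.width_px


@dataclass
class LaneProfile:
    """Optical density per pixel row along one lane."""

    lane_id: str
    row_px: np.ndarray
    od: np.ndarray
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.row_px = np.asarray(self.row_px, dtype=int)
        self.od = np.asarray(self.od, dtype=float)
        if self.row_px.shape != self.od.shape:
            raise ValueError("row_px and od must have equal length")


@dataclass
class LadderCalibration:
    """Cubic map from pixel row to fragment size kb(row) = c0 + c1 r + c2 r^2 + c3 r^3."""

    coeffs: np.ndarray
    window_kb: tuple[float, float] = DEFAULT_WINDOW_KB
    fit_rmse_kb: float = 0.0
    source_peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (4,):
            raise ValueError("calibration needs exactly 4 cubic coefficients")
        if not self.window_kb[0] < self.window_kb[1]:
            raise ValueError("window low must be below window high")

    def kb_at(self, row: np.ndarray | float) -> np.ndarray | float:
        r = np.asarray(row, dtype=float)
        c0, c1, c2, c3 = self.coeffs
        out = c0 + c1 * r + c2 * r**2 + c3 * r**3
        return float(out) if np.isscalar(row) else out

    def row_at(self, kb: float, row_range: tuple[int, int]) -> float:
        """Invert the migration map for one kb value by dense-grid bisection."""
        rows = np.arange(row_range[0], row_range[1], dtype=float)
        vals = self.kb_at(rows)
        order = np.argsort(vals)
        return float(np.interp(kb, vals[order], rows[order]))

    def is_monotone_over(self, rows: np.ndarray) -> bool:
        vals = self.kb_at(np.asarray(rows, dtype=float))
        d = np.diff(vals)
        return bool(np.all(d > 0) or np.all(d < 0))


@dataclass
class TLDistribution:
    """Per-individual telomere-length distribution.

    ``positions_kb`` are fragment sizes (one per retained pixel row) and
    ``weights`` the background-subtracted OD values, interpreted on the
    molecule-count scale.
    """

    individual_id: str
    positions_kb: np.ndarray
    weights: np.ndarray
    window_kb: tuple[float, float] = DEFAULT_WINDOW_KB

    def __post_init__(self) -> None:
        self.positions_kb = np.asarray(self.positions_kb, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.positions_kb.shape != self.weights.shape:
            raise ValueError("positions and weights must have equal length")
        if not np.all(np.isfinite(self.positions_kb)):
            raise ValueError("non-finite positions")
        if np.any(self.weights < 0):
            raise ValueError("negative weights")
        if self.weights.sum() <= 0:
            raise ValueError("weights must have positive sum")
        lo, hi = self.window_kb
        if np.any((self.positions_kb < lo) | (self.positions_kb > hi)):
            raise ValueError("positions outside the analysis window")

    def total_weight(self) -> float:
        return float(self.weights.sum())


def extract_lane_profile(image: GelImage, lane: LaneSpec) -> LaneProfile:
    """Average pixel intensity across the lane width at every row.

    Emulates measuring OD along a line centered on the lane, averaged over
    ``width_px`` columns.
    """
    lo, hi = lane.columns()
    if lo < 0 or hi > image.n_cols:
        raise ValueError(
            f"lane {lane.lane_id} columns [{lo}, {hi}) outside image width {image.n_cols}"
        )
    od = image.pixels[:, lo:hi].mean(axis=1)
    return LaneProfile(lane.lane_id, np.arange(image.n_rows), od)


def detect_ladder_peaks(profile: LaneProfile, n_expected: int) -> np.ndarray:
    """Return the rows of the ``n_expected`` most prominent local maxima, sorted by row.

    Ties in prominence are broken toward the lower row index so that repeated
    runs give identical calibrations.
    """
    if n_expected < 4:
        raise ValueError("need at least 4 ladder bands for a cubic calibration")
    peaks, props = find_peaks(profile.od, prominence=0.0, plateau_size=(1, None))
    # report the left edge of flat-topped bands: lower row wins on ties
    rows = props.get("left_edges", peaks)
    prom = props["prominences"]
    if len(rows) < n_expected:
        raise ValueError(
            f"found only {len(rows)} ladder peaks, expected {n_expected}"
        )
    order = np.lexsort((rows, -prom))[:n_expected]
    return np.sort(rows[order])


def fit_ladder_calibration(
    peaks: Sequence[tuple[float, float]],
    window_kb: tuple[float, float] = DEFAULT_WINDOW_KB,
    log_scale: bool = False,
) -> LadderCalibration:
    """Least-squares cubic of fragment size on pixel row through ladder bands.

    ``peaks`` are (row_px, kb) pairs.  The fitted map must be strictly
    monotone over the row range spanned by the analysis window, otherwise the
    gel is unusable for quantification and an error is raised.

    ``log_scale`` fits the cubic to log10(kb) instead; off by default since
    the calibration is conventionally a direct pixel-to-kb polynomial.
    """
    pts = sorted(peaks)  # order invariance
    if len(pts) < 4:
        raise ValueError(f"need >= 4 ladder peaks, got {len(pts)}")
    rows = np.array([p[0] for p in pts], dtype=float)
    kbs = np.array([p[1] for p in pts], dtype=float)
    if len(np.unique(rows)) < len(rows):
        raise ValueError("ladder peaks must have distinct rows")
    target = np.log10(kbs) if log_scale else kbs
    design = np.vander(rows, 4, increasing=True)
    coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
    fitted = design @ coeffs
    if log_scale:
        resid = kbs - 10.0**fitted
        coeffs = _refit_linear_scale(rows, kbs)  # store an equivalent kb-scale cubic
    else:
        resid = kbs - fitted
    cal = LadderCalibration(
        coeffs=coeffs,
        window_kb=window_kb,
        fit_rmse_kb=float(np.sqrt(np.mean(resid**2))),
        source_peaks=[(float(r), float(k)) for r, k in pts],
    )
    grid = np.linspace(rows.min(), rows.max(), 512)
    if not cal.is_monotone_over(grid):
        raise ValueError("fitted migration map is not monotone over the ladder range")
    return cal


def _refit_linear_scale(rows: np.ndarray, kbs: np.ndarray) -> np.ndarray:
    design = np.vander(rows, 4, increasing=True)
    coeffs, *_ = np.linalg.lstsq(design, kbs, rcond=None)
    return coeffs


def estimate_background(
    image: GelImage, lane: LaneSpec, below_marker_row: int
) -> float:
    """Mean intensity along a horizontal line just below the lowest size marker,
    restricted to the lane's width."""
    if not 0 <= below_marker_row < image.n_rows:
        raise ValueError(
            f"background row {below_marker_row} outside image height {image.n_rows}"
        )
    lo, hi = lane.columns()
    if lo < 0 or hi > image.n_cols:
        raise ValueError(f"lane {lane.lane_id} outside image")
    return float(image.pixels[below_marker_row, lo:hi].mean())


def profile_to_distribution(
    profile: LaneProfile,
    cal: LadderCalibration,
    background: float,
    individual_id: str,
) -> TLDistribution:
    """Calibrate, background-subtract and window one lane profile.

    Per retained row ``r``: position = kb(r), weight = max(od[r] - background, 0).
    Rows mapping outside the analysis window are discarded; in-window rows
    whose OD falls at or below background are kept with weight 0 so the
    support grid stays regular.
    """
    kb = cal.kb_at(profile.row_px)
    lo, hi = cal.window_kb
    keep = (kb >= lo) & (kb <= hi)
    if not np.any(keep):
        raise ValueError("no rows map inside the analysis window")
    weights = np.clip(profile.od[keep] - background, 0.0, None)
    if weights.sum() <= 0:
        raise ValueError(f"empty lane: no OD above background for {individual_id!r}")
    return TLDistribution(
        individual_id=individual_id,
        positions_kb=kb[keep],
        weights=weights,
        window_kb=cal.window_kb,
    )


def quantify_gel(
    image: GelImage,
    lanes: Sequence[LaneSpec],
    ladder_sizes_kb: Sequence[float],
    below_marker_row: int,
    window_kb: tuple[float, float] = DEFAULT_WINDOW_KB,
) -> tuple[LadderCalibration, dict[str, TLDistribution]]:
    """Full single-gel pipeline: calibrate from the central ladder lane, then
    quantify every sample/standard lane.

    Ladder bands and ``ladder_sizes_kb`` are matched in order: the topmost
    band (lowest row) is the largest fragment.
    """
    ladder_lanes = [ln for ln in lanes if ln.kind == "ladder"]
    if not ladder_lanes:
        raise ValueError("no ladder lane in the lane layout")
    central = ladder_lanes[len(ladder_lanes) // 2]
    prof = extract_lane_profile(image, central)
    sizes = np.sort(np.asarray(ladder_sizes_kb, dtype=float))[::-1]
    rows = detect_ladder_peaks(prof, n_expected=len(sizes))
    cal = fit_ladder_calibration(list(zip(rows.tolist(), sizes.tolist())), window_kb)
    out: dict[str, TLDistribution] = {}
    for ln in lanes:
        if ln.kind == "ladder":
            continue
        bg = estimate_background(image, ln, below_marker_row)
        lane_prof = extract_lane_profile(image, ln)
        out[ln.lane_id] = profile_to_distribution(lane_prof, cal, bg, ln.lane_id)
    return cal, out
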
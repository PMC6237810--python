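"""Gel quantification: marker detection, size calibration, diagnostic
regions and background-corrected fraction percentages.

The five diagnostic regions follow the band geometry of the Cy5 marker:

* ``undigested`` — box from the well down/right to the upper/left edges of
  the 3000 bp band (DNA at limiting mobility).
* ``dsDNA`` — diagonal band along the marker arc between the 1000 bp upper
  edge and the 100 bp lower edge.
* ``behind`` — the dsDNA band translated left by its own width (interstrand
  crosslinked strands, roughly doubled effective length).
* ``front`` — the flank right of the arc, from the 100 bp band up to the
  horizontal through the 2000 bp band (bent duplexes and single strands).
* ``ssb_streak`` — the horizontal band from the unmigrated DNA position to
  the point vertically over the 100 bp band.

Regions are clipped to be mutually disjoint in the priority order
undigested > dsDNA > behind > front > ssb_streak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from skimage.draw import polygon2mask
from skimage.feature import peak_local_max
from skimage.filters import gaussian

from .electrophoresis import GelImage, LadderSpec

__all__ = [
    "LadderBand",
    "LadderBandSet",
    "SizeCalibration",
    "RegionSet",
    "FractionReport",
    "SizeDistribution",
    "detect_ladder_bands",
    "fit_size_calibration",
    "build_regions",
    "quantify_fractions",
    "estimate_size_distribution",
    "detect_ladder_peaks",
    "NoLadderSignalError",
    "MissingBandError",
    "NoSignalError",
    "UnsupportedRegionError",
]

REQUIRED_BAND_SIZES = (100, 1000, 2000, 3000)
REGION_PRIORITY = ("undigested", "dsDNA", "behind", "front", "ssb_streak")


class NoLadderSignalError(ValueError):
    """The Cy5 channel carries no signal above background."""


class MissingBandError(ValueError):
    """A marker band required for region construction was not detected."""


class NoSignalError(ValueError):
    """No region has signal above background."""


class UnsupportedRegionError(ValueError):
    """Size estimation is undefined for the requested region."""


@dataclass(frozen=True)
class LadderBand:
    size: int
    cx: float
    cy: float
    left: float
    right: float
    top: float
    bottom: float
    intensity: float


@dataclass
class LadderBandSet:
    bands: list[LadderBand]

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands, key=lambda b: b.size)
        xs = [b.cx for b in self.bands]
        if any(x1 <= x0 for x0, x1 in zip(xs[1:], xs[:-1])):
            # centroids must be strictly decreasing in x as size grows
            raise MissingBandError("band centroids are not strictly ordered in x with size")

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def get(self, size: int) -> LadderBand:
        for b in self.bands:
            if b.size == size:
                return b
        raise MissingBandError(f"required marker band {size} bp not present")


def _background_stats(channel: np.ndarray) -> tuple[float, float]:
    med = float(np.median(channel))
    mad = float(np.median(np.abs(channel - med)))
    return med, 1.4826 * mad


def detect_ladder_bands(image: GelImage, ladder: LadderSpec) -> LadderBandSet:
    """Find marker bands in the Cy5 channel and match them to nominal sizes.

    Local maxima above ``background + 5 * noise`` are matched to the nominal
    sizes by x-order (largest x = smallest size); band edges are taken at the
    half-maximum contour along each axis.
    """
    ch = image.cy5_channel.astype(np.float64)
    bg, noise = _background_stats(ch)
    noise = max(noise, 1e-9)
    if ch.max() <= bg + 5 * noise:
        raise NoLadderSignalError("no ladder signal above background in the Cy5 channel")
    smoothed = gaussian(ch, sigma=1.0, preserve_range=True)
    n_expected = len(ladder.band_sizes)
    coords = peak_local_max(
        smoothed, min_distance=6, threshold_abs=bg + 5 * noise, exclude_border=False
    )
    if len(coords) > n_expected:
        vals = smoothed[coords[:, 0], coords[:, 1]]
        coords = coords[np.argsort(vals)[::-1][:n_expected]]
    if len(coords) < n_expected:
        raise MissingBandError(
            f"detected {len(coords)} marker bands, expected {n_expected}"
        )
    # x-order matching: nominal sizes ascending <-> centroid x descending
    coords = coords[np.argsort(coords[:, 1])[::-1]]
    bands = []
    for size, (py, px) in zip(ladder.band_sizes, coords):
        cy, cx = _refine_centroid(ch, bg, py, px, radius=7)
        peak_val = smoothed[py, px]
        half = bg + 0.5 * (peak_val - bg)
        left = _walk_edge(smoothed, py, px, 0, -1, half)
        right = _walk_edge(smoothed, py, px, 0, +1, half)
        top = _walk_edge(smoothed, py, px, -1, 0, half)
        bottom = _walk_edge(smoothed, py, px, +1, 0, half)
        box = ch[int(top): int(bottom) + 1, int(left): int(right) + 1]
        integ = float(box.sum() - bg * box.size)
        bands.append(LadderBand(size, cx, cy, left, right, top, bottom, integ))
    band_set = LadderBandSet(bands)
    for size in REQUIRED_BAND_SIZES:
        if size in ladder.band_sizes:
            band_set.get(size)
    return band_set


def _refine_centroid(ch: np.ndarray, bg: float, py: int, px: int, radius: int) -> tuple[float, float]:
    h, w = ch.shape
    y0, y1 = max(0, py - radius), min(h, py + radius + 1)
    x0, x1 = max(0, px - radius), min(w, px + radius + 1)
    win = np.clip(ch[y0:y1, x0:x1] - bg, 0.0, None)
    tot = win.sum()
    if tot <= 0:
        return float(py), float(px)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    return float((ys * win).sum() / tot), float((xs * win).sum() / tot)


def _walk_edge(ch: np.ndarray, py: int, px: int, dy: int, dx: int, half: float) -> float:
    h, w = ch.shape
    y, x = py, px
    while 0 <= y + dy < h and 0 <= x + dx < w and ch[y + dy, x + dx] > half:
        y, x = y + dy, x + dx
    return float(y if dx == 0 else x)


# ---------------------------------------------------------------------------
# size calibration
# ---------------------------------------------------------------------------


def _interp_extrap(q: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation with linear end-slope extrapolation.

    ``xs`` must be strictly increasing.
    """
    q = np.asarray(q, dtype=float)
    out = np.interp(q, xs, ys)
    lo = q < xs[0]
    hi = q > xs[-1]
    if lo.any():
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        out = np.where(lo, ys[0] + slope * (q - xs[0]), out)
    if hi.any():
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out = np.where(hi, ys[-1] + slope * (q - xs[-1]), out)
    return out


@dataclass
class SizeCalibration:
    """Monotone piecewise-linear maps between log-size and gel coordinates."""

    sizes: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    @property
    def validity_range(self) -> tuple[float, float]:
        return float(self.sizes[0]), float(self.sizes[-1])

    def size_from_x(self, x) -> np.ndarray | float:
        # x decreases with size: interpolate on ascending x
        logs = _interp_extrap(np.asarray(x, float), self.xs[::-1], np.log(self.sizes[::-1]))
        return np.exp(logs)

    def size_from_y(self, y) -> np.ndarray | float:
        logs = _interp_extrap(np.asarray(y, float), self.ys[::-1], np.log(self.sizes[::-1]))
        return np.exp(logs)

    def x_from_size(self, size) -> np.ndarray | float:
        return _interp_extrap(np.log(np.asarray(size, float)), np.log(self.sizes), self.xs)

    def y_from_size(self, size) -> np.ndarray | float:
        return _interp_extrap(np.log(np.asarray(size, float)), np.log(self.sizes), self.ys)

    def is_extrapolated_x(self, x) -> np.ndarray | bool:
        return (np.asarray(x, float) < self.xs[-1]) | (np.asarray(x, float) > self.xs[0])

    def is_extrapolated_size(self, size) -> np.ndarray | bool:
        s = np.asarray(size, float)
        return (s < self.sizes[0]) | (s > self.sizes[-1])


def fit_size_calibration(bands: LadderBandSet) -> SizeCalibration:
    """Fit the monotone log-size vs coordinate maps on detected bands."""
    if len(bands) < 4:
        raise ValueError("need at least 4 marker bands to calibrate")
    sizes = np.array([b.size for b in bands], dtype=float)
    xs = np.array([b.cx for b in bands], dtype=float)
    ys = np.array([b.cy for b in bands], dtype=float)
    if not (np.diff(xs) < 0).all() or not (np.diff(ys) < 0).all():
        raise ValueError("non-monotone ladder: band coordinates do not decrease with size")
    return SizeCalibration(sizes=sizes, xs=xs, ys=ys)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


@dataclass
class RegionSet:
    polygons: dict[str, list[tuple[float, float]]]
    masks: dict[str, np.ndarray]
    background_box: tuple[int, int, int, int]  # x0, y0, x1, y1 (half-open)
    shape: tuple[int, int]

    def mask(self, name: str) -> np.ndarray:
        return self.masks[name]


def _rect(x0: float, y0: float, x1: float, y1: float) -> list[tuple[float, float]]:
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


def build_regions(
    bands: LadderBandSet,
    image: GelImage,
    arc_halfwidth_px: Optional[float] = None,
    background_box: Optional[tuple[int, int, int, int]] = None,
) -> RegionSet:
    """Construct the five diagnostic regions from the marker geometry.

    The arc line is fitted through all band centroids.  The dsDNA band's
    half-width defaults to half the x-spacing between the two smallest
    bands, i.e. the displacement of a species of twice the length, so that
    its left translate is centred on doubled-length (crosslinked) species.
    """
    h, w = image.shape
    b100 = bands.get(100)
    b1000 = bands.get(1000)
    b2000 = bands.get(2000)
    b3000 = bands.get(3000)
    if arc_halfwidth_px is None:
        sizes = sorted(b.size for b in bands)
        if len(sizes) >= 2 and sizes[1] <= 2 * sizes[0]:
            arc_halfwidth_px = 0.5 * abs(bands.get(sizes[0]).cx - bands.get(sizes[1]).cx) * (
                math.log(2) / math.log(sizes[1] / sizes[0])
            )
        else:
            arc_halfwidth_px = 3.0 * max(b.right - b.left for b in bands)
    hw = float(arc_halfwidth_px)

    ys = np.array([b.cy for b in bands], float)
    xs = np.array([b.cx for b in bands], float)
    slope, intercept = np.polyfit(ys, xs, 1)

    def arc_x(y: float) -> float:
        return slope * y + intercept

    y_top, y_bot = b1000.top, b100.bottom
    polys: dict[str, list[tuple[float, float]]] = {}
    polys["undigested"] = _rect(0, 0, b3000.left, b3000.top)
    polys["dsDNA"] = [
        (arc_x(y_top) - hw, y_top),
        (arc_x(y_top) + hw, y_top),
        (arc_x(y_bot) + hw, y_bot),
        (arc_x(y_bot) - hw, y_bot),
    ]
    polys["behind"] = [(max(0.0, x - 2 * hw), y) for x, y in polys["dsDNA"]]
    y_2000 = b2000.cy
    x_right = b100.cx + hw
    polys["front"] = [
        (arc_x(y_2000) + hw, y_2000),
        (x_right, y_2000),
        (x_right, y_bot),
        (arc_x(y_bot) + hw, y_bot),
    ]
    polys["ssb_streak"] = _rect(b3000.left, 0, x_right, b3000.top)

    masks: dict[str, np.ndarray] = {}
    taken = np.zeros((h, w), dtype=bool)
    for name in REGION_PRIORITY:
        pts = np.array([(y, x) for x, y in polys[name]], dtype=float)
        m = polygon2mask((h, w), pts)
        m &= ~taken
        taken |= m
        masks[name] = m

    if background_box is None:
        background_box = _auto_background_box(image.stain_channel, taken)
    else:
        x0, y0, x1, y1 = background_box
        if taken[y0:y1, x0:x1].any():
            raise ValueError("background box overlaps a diagnostic region")
    return RegionSet(polygons=polys, masks=masks, background_box=background_box, shape=(h, w))


def split_front_region(regions: RegionSet, y_boundary: float) -> RegionSet:
    """Optional sub-split of the merged front region into an upper and lower
    y-band (bent duplexes vs short single strands); not part of the
    canonical five-region report."""
    front = regions.mask("front")
    h, w = regions.shape
    rows = np.arange(h)[:, None]
    masks = dict(regions.masks)
    masks["front_upper"] = front & (rows < y_boundary)
    masks["front_lower"] = front & (rows >= y_boundary)
    polys = dict(regions.polygons)
    return RegionSet(
        polygons=polys, masks=masks, background_box=regions.background_box, shape=regions.shape
    )


def _auto_background_box(
    channel: np.ndarray, taken: np.ndarray, size: int = 64, stride: int = 32
) -> tuple[int, int, int, int]:
    """Minimum-mean window over the image that avoids all regions."""
    h, w = channel.shape
    best, best_box = None, None
    for y0 in range(0, h - size + 1, stride):
        for x0 in range(0, w - size + 1, stride):
            if taken[y0: y0 + size, x0: x0 + size].any():
                continue
            m = float(channel[y0: y0 + size, x0: x0 + size].mean())
            if best is None or m < best:
                best, best_box = m, (x0, y0, x0 + size, y0 + size)
    if best_box is None:
        raise ValueError("could not place a DNA-free background box")
    return best_box


# ---------------------------------------------------------------------------
# fractions
# ---------------------------------------------------------------------------


@dataclass
class FractionReport:
    regions: dict[str, dict[str, float]]  # raw, area, corrected, percentage
    background_per_px: float

    @property
    def percentages(self) -> dict[str, float]:
        return {k: v["percentage"] for k, v in self.regions.items()}

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame.from_dict(self.regions, orient="index").rename_axis("region")

    def to_dict(self) -> dict:
        return {"background_per_px": self.background_per_px, "regions": self.regions}


def quantify_fractions(
    image: GelImage,
    regions: RegionSet,
    background_box: Optional[tuple[int, int, int, int]] = None,
) -> FractionReport:
    """Background-corrected relative density per region, in percent.

    corrected = sum(intensity) - mean_background_per_px * area, clipped at 0;
    percentages normalise corrected densities to 100.
    """
    ch = image.stain_channel.astype(np.float64)
    x0, y0, x1, y1 = background_box or regions.background_box
    box = ch[y0:y1, x0:x1]
    if box.size == 0:
        raise ValueError("background box is empty")
    bg = float(box.mean())
    out: dict[str, dict[str, float]] = {}
    for name in REGION_PRIORITY:
        m = regions.mask(name)
        area = float(m.sum())
        raw = float(ch[m].sum())
        corrected = max(0.0, raw - bg * area)
        out[name] = {"raw": raw, "area": area, "corrected": corrected, "percentage": 0.0}
    total = sum(v["corrected"] for v in out.values())
    if total <= 0:
        raise NoSignalError("no signal above background in any region")
    for v in out.values():
        v["percentage"] = 100.0 * v["corrected"] / total
    return FractionReport(regions=out, background_per_px=bg)


# ---------------------------------------------------------------------------
# size distributions and peak calling
# ---------------------------------------------------------------------------


@dataclass
class SizeDistribution:
    sizes: np.ndarray  # ascending, nt
    intensities: np.ndarray  # background-corrected, clipped at 0
    extrapolated: np.ndarray  # per-entry flag
    region: str = ""

    def __len__(self) -> int:
        return len(self.sizes)

    @property
    def mode(self) -> Optional[float]:
        if len(self.sizes) == 0 or self.intensities.sum() <= 0:
            return None
        return float(self.sizes[int(np.argmax(self.intensities))])

    def quantile(self, q: float) -> Optional[float]:
        tot = self.intensities.sum()
        if len(self.sizes) == 0 or tot <= 0:
            return None
        cum = np.cumsum(self.intensities) / tot
        return float(self.sizes[int(np.searchsorted(cum, q))])


def estimate_size_distribution(
    image: GelImage, regions: RegionSet, region: str, cal: SizeCalibration
) -> SizeDistribution:
    """Column-wise background-corrected intensity of a region, binned by the
    size assigned to each column by the x-calibration.

    The unresolved ``undigested`` fraction has no defined size distribution
    and raises :class:`UnsupportedRegionError`.
    """
    if region == "undigested":
        raise UnsupportedRegionError(
            "size estimation is not defined for the unresolved undigested fraction"
        )
    m = regions.mask(region)
    ch = image.stain_channel.astype(np.float64)
    x0, y0, x1, y1 = regions.background_box
    bg = float(ch[y0:y1, x0:x1].mean())
    cols = np.flatnonzero(m.any(axis=0))
    if cols.size == 0:
        return SizeDistribution(np.array([]), np.array([]), np.array([], bool), region)
    counts = m[:, cols].sum(axis=0)
    sums = np.array([ch[m[:, c], c].sum() for c in cols])
    corrected = np.clip(sums - bg * counts, 0.0, None)
    sizes = np.atleast_1d(cal.size_from_x(cols.astype(float)))
    extrap = np.atleast_1d(cal.is_extrapolated_x(cols.astype(float)))
    order = np.argsort(sizes)
    return SizeDistribution(sizes[order], corrected[order], extrap[order], region)


def detect_ladder_peaks(
    dist: SizeDistribution, min_prominence: Optional[float] = None
) -> list[float]:
    """Prominence-based peak calling on a size distribution; peak sizes are
    returned in increasing order (empty list if featureless)."""
    if len(dist) == 0:
        return []
    inten = dist.intensities
    if inten.max() <= 0:
        return []
    if min_prominence is None:
        min_prominence = 0.1 * float(inten.max())
    idx, _ = find_peaks(inten, prominence=min_prominence)
    return sorted(float(dist.sizes[i]) for i in idx)
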
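"""Impact-induced chondrocyte death quantification from live/dead micrographs.

The pipeline mirrors a standard confocal viability analysis: each channel
of the Z-stack is collapsed by maximum-intensity projection, thresholded
by Otsu's method, and segmented by a distance-transform-seeded watershed;
cells are classified live or dead from their per-channel mean
intensities; the pre- and post-impact frames are aligned by integer-
translation normalized cross-correlation; and the impact-induced death
area is the increase in dead-cell area inside the registered overlap
region.

Death-area definition (stated prominently because the quantity has no
unique definition): ``death_area = post dead area − pre dead area``
within the overlap ROI, clamped at zero, with the raw signed value
retained; ``death_area_fraction`` normalizes by the pre-impact live area
in the same ROI. Coordinates are 0-based (row, col) pixel indices; areas
are reported in μm² via ``pixel_size²``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max
from skimage.segmentation import relabel_sequential, watershed

from .stack import MicrographStack

LIVE, DEAD = "live", "dead"


# --------------------------------------------------------------------------
# projection and thresholding
# --------------------------------------------------------------------------

def max_intensity_projection(stack: MicrographStack, channel: str) -> np.ndarray:
    """Per-pixel maximum over Z-planes of one channel."""
    return stack.channel(channel).max(axis=0)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance of the intensity histogram.

    For integer images whose value span fits in ``nbins`` levels the
    histogram has one bin per integer level and the returned threshold is
    an exact level: foreground is ``image > threshold`` and every one of
    the ≤ ``nbins`` candidate splits is evaluated. Float images use an
    ``nbins``-bin histogram over the observed min–max range and the
    returned threshold is the bin edge of the best split. Ties take the
    lowest threshold. A constant image has no separable classes and
    raises ``ValueError``.
    """
    vals = np.asarray(image).ravel()
    vmin, vmax = vals.min(), vals.max()
    if vmin == vmax:
        raise ValueError("constant image: no separable intensity classes")

    integer_like = np.issubdtype(vals.dtype, np.integer) and (int(vmax) - int(vmin)) < nbins
    if integer_like:
        levels = np.arange(int(vmin), int(vmax) + 1, dtype=float)
        hist = np.bincount((vals - int(vmin)).astype(np.int64),
                           minlength=levels.size).astype(float)
        centers = levels
        # candidate t = levels[i] puts pixels <= t in the lower class
        thresholds = levels[:-1]
    else:
        hist, edges = np.histogram(vals, bins=nbins, range=(vmin, vmax))
        hist = hist.astype(float)
        centers = 0.5 * (edges[:-1] + edges[1:])
        thresholds = edges[1:-1]

    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    s0 = np.cumsum(hist * centers)[:-1]
    s1 = (hist * centers).sum() - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s0 / w0
        m1 = s1 / w1
        sigma_b = w0 * w1 * (m0 - m1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    return float(thresholds[int(np.argmax(sigma_b))])


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

@dataclass
class CellSegmentation:
    """Label image plus a per-cell property table.

    ``labels`` is 0 for background and k for cell k (contiguous positive
    integers). ``cells`` has one row per label with centroid (pixels),
    area (μm² and pixels), per-channel mean intensity columns
    (``mean_<channel>``) and, after classification, ``viability``.
    """

    labels: np.ndarray
    cells: pd.DataFrame
    pixel_size: float
    channel_names: tuple[str, ...] = ()

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def total_area_um2(self) -> float:
        return float(self.cells["area_um2"].sum()) if self.n_cells else 0.0


def segment_cells(
    foreground: np.ndarray,
    intensity_images: dict[str, np.ndarray] | None = None,
    pixel_size: float = 1.0,
    min_cell_area: float = 20.0,
    min_separation_um: float = 5.0,
) -> CellSegmentation:
    """Distance-transform watershed segmentation of a binary foreground.

    Watershed basins are seeded at local maxima of the Euclidean distance
    transform separated by at least ``min_separation_um`` (default: an
    expected cell radius), which splits touching cells. Regions below
    ``min_cell_area`` (μm², default 20 — debris exclusion) are discarded
    and labels relabeled contiguously. An empty foreground yields an
    empty segmentation, not an error.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if min_cell_area < 0:
        raise ValueError("min_cell_area must be >= 0")
    intensity_images = intensity_images or {}

    empty = CellSegmentation(
        labels=np.zeros(foreground.shape, dtype=np.int32),
        cells=_empty_cells_frame(intensity_images),
        pixel_size=pixel_size,
        channel_names=tuple(intensity_images),
    )
    if not foreground.any():
        return empty

    dist = ndimage.distance_transform_edt(foreground)
    min_dist_px = max(1, int(round(min_separation_um / pixel_size)))
    coords = peak_local_max(dist, min_distance=min_dist_px, labels=foreground,
                            exclude_border=False)
    if coords.size == 0:
        return empty
    seeds = np.zeros(foreground.shape, dtype=bool)
    seeds[tuple(coords.T)] = True
    markers, _ = ndimage.label(seeds)
    labels = watershed(-dist, markers, mask=foreground)

    # area filter in μm², then contiguous relabeling
    min_area_px = min_cell_area / pixel_size**2
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_area_px]
    labels = np.where(np.isin(labels, keep), labels, 0)
    labels, _, _ = relabel_sequential(labels)
    labels = labels.astype(np.int32)
    if labels.max() == 0:
        return empty

    n = int(labels.max())
    index = np.arange(1, n + 1)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, index)
    areas_px = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels, index)
    table = {
        "label": index,
        "centroid_row": [c[0] for c in centroids],
        "centroid_col": [c[1] for c in centroids],
        "area_px": areas_px.astype(int),
        "area_um2": areas_px * pixel_size**2,
    }
    for name, img in intensity_images.items():
        table[f"mean_{name}"] = ndimage.mean(img, labels, index)
    return CellSegmentation(
        labels=labels,
        cells=pd.DataFrame(table),
        pixel_size=pixel_size,
        channel_names=tuple(intensity_images),
    )


def _empty_cells_frame(intensity_images: dict) -> pd.DataFrame:
    cols = ["label", "centroid_row", "centroid_col", "area_px", "area_um2"]
    cols += [f"mean_{name}" for name in intensity_images]
    return pd.DataFrame({c: [] for c in cols})


def classify_viability(
    seg: CellSegmentation,
    live_image: np.ndarray,
    dead_image: np.ndarray,
    tie_class: str = DEAD,
) -> CellSegmentation:
    """Assign each segmented cell a live/dead class.

    Each channel is scaled by its own Otsu threshold so the two dyes are
    comparable despite different gains; a cell is dead when its scaled
    dead-channel mean is at least its scaled live-channel mean (ties go
    to ``tie_class``, dead by default — conservative for an injury
    assay). A constant channel carries no signal: its scaled score is 0.
    """

    def scale(img: np.ndarray) -> float:
        try:
            return otsu_threshold(img)
        except ValueError:  # constant channel, e.g. no dead cells at all
            return np.inf

    t_live, t_dead = scale(live_image), scale(dead_image)
    cells = seg.cells.copy()
    if seg.n_cells == 0:
        cells["viability"] = pd.Series(dtype=object)
        return CellSegmentation(seg.labels, cells, seg.pixel_size, seg.channel_names)
    index = cells["label"].to_numpy()
    mean_live = ndimage.mean(live_image, seg.labels, index)
    mean_dead = ndimage.mean(dead_image, seg.labels, index)
    score_live = np.where(np.isfinite(t_live), mean_live / t_live, 0.0)
    score_dead = np.where(np.isfinite(t_dead), mean_dead / t_dead, 0.0)
    if tie_class == DEAD:
        is_dead = score_dead >= score_live
    else:
        is_dead = score_dead > score_live
    cells["score_live"] = score_live
    cells["score_dead"] = score_dead
    cells["viability"] = np.where(is_dead, DEAD, LIVE)
    return CellSegmentation(seg.labels, cells, seg.pixel_size, seg.channel_names)


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------

@dataclass
class RoiAlignment:
    """Rigid integer translation between pre and post frames.

    ``offset`` is the (dy, dx) such that content at pre pixel (y, x)
    appears at post pixel (y+dy, x+dx). ``roi`` is the overlap rectangle
    (r0, r1, c0, c1), half-open, in pre-frame coordinates. ``score`` is
    the normalized cross-correlation at the chosen offset.
    """

    offset: tuple[int, int]
    roi: tuple[int, int, int, int]
    score: float
    low_confidence: bool = False

    def roi_in_post(self) -> tuple[int, int, int, int]:
        r0, r1, c0, c1 = self.roi
        dy, dx = self.offset
        return (r0 + dy, r1 + dy, c0 + dx, c1 + dx)


def _sat(a: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero border row/col."""
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=s[1:, 1:])
    return s


def _rect_sum(sat: np.ndarray, r0, r1, c0, c1):
    """Sum over half-open rectangle [r0:r1, c0:c1]; arguments may be arrays."""
    return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]


def register_roi(
    pre: np.ndarray,
    post: np.ndarray,
    max_shift: int = 50,
    score_floor: float = 0.2,
) -> RoiAlignment:
    """Find the integer translation maximizing normalized cross-correlation.

    Exhaustive over all shifts within ±``max_shift`` px in each axis.
    The raw cross term is computed in one FFT correlation; per-shift
    overlap means and variances come from summed-area tables, so the
    search is exact, not an approximation. Ties prefer the smallest
    offset (by magnitude, then row, then column). A best score below
    ``score_floor`` sets ``low_confidence`` (and warns) but the offset is
    still returned.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post images must share dimensions")
    h, w = pre.shape
    m = int(max_shift)
    if m >= min(h, w):
        raise ValueError("max_shift must be smaller than the image")

    # cross(dy,dx) = sum_y,x pre[y,x] * post[y+dy, x+dx]
    full = fftconvolve(post, pre[::-1, ::-1], mode="full")
    dys, dxs = np.arange(-m, m + 1), np.arange(-m, m + 1)
    DY, DX = np.meshgrid(dys, dxs, indexing="ij")
    cross = full[h - 1 + DY, w - 1 + DX]

    sat_p, sat_p2 = _sat(pre), _sat(pre**2)
    sat_q, sat_q2 = _sat(post), _sat(post**2)

    # overlap rectangle in pre coords for shift (dy,dx)
    r0, r1 = np.maximum(0, -DY), h - np.maximum(0, DY)
    c0, c1 = np.maximum(0, -DX), w - np.maximum(0, DX)
    n = (r1 - r0) * (c1 - c0)
    sp = _rect_sum(sat_p, r0, r1, c0, c1)
    sp2 = _rect_sum(sat_p2, r0, r1, c0, c1)
    sq = _rect_sum(sat_q, r0 + DY, r1 + DY, c0 + DX, c1 + DX)
    sq2 = _rect_sum(sat_q2, r0 + DY, r1 + DY, c0 + DX, c1 + DX)

    with np.errstate(invalid="ignore", divide="ignore"):
        num = cross - sp * sq / n
        var_p = sp2 - sp**2 / n
        var_q = sq2 - sq**2 / n
        ncc = num / np.sqrt(var_p * var_q)
    ncc[(var_p <= 0) | (var_q <= 0)] = -np.inf
    ncc = np.clip(ncc, -1.0, 1.0)

    best = np.max(ncc)
    # deterministic tie-break: smallest |offset|, then row, then col
    cand = np.argwhere(ncc >= best - 1e-12)
    order = np.lexsort((cand[:, 1], cand[:, 0],
                        np.abs(dys[cand[:, 0]]) + np.abs(dxs[cand[:, 1]])))
    iy, ix = cand[order[0]]
    dy, dx = int(dys[iy]), int(dxs[ix])

    roi = (max(0, -dy), h - max(0, dy), max(0, -dx), w - max(0, dx))
    low = bool(best < score_floor)
    if low:
        warnings.warn(
            f"registration score {best:.3f} below floor {score_floor}; "
            "offset may be unreliable",
            stacklevel=2,
        )
    return RoiAlignment(offset=(dy, dx), roi=roi, score=float(best), low_confidence=low)


# --------------------------------------------------------------------------
# quantification
# --------------------------------------------------------------------------

@dataclass
class ViabilityResult:
    """Pre/post viability accounting inside the registered overlap ROI.

    ``death_area_um2`` (post dead − pre dead area, clamped at 0) is the
    headline impact-induced death quantity; the raw signed difference and
    the fraction of the pre-impact live area are also reported.
    """

    pre_live_count: int
    pre_dead_count: int
    post_live_count: int
    post_dead_count: int
    pre_live_area_um2: float
    pre_dead_area_um2: float
    post_live_area_um2: float
    post_dead_area_um2: float
    death_area_um2: float
    death_area_raw_um2: float
    death_area_fraction: float
    alignment: RoiAlignment | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "alignment"}
        if self.alignment is not None:
            d["alignment"] = {
                "offset": list(self.alignment.offset),
                "roi": list(self.alignment.roi),
                "score": self.alignment.score,
                "low_confidence": self.alignment.low_confidence,
            }
        return d


def _roi_class_stats(
    seg: CellSegmentation, roi: tuple[int, int, int, int]
) -> dict[str, tuple[int, float]]:
    """(count, area μm²) per viability class inside a rectangle.

    Counts use cell centroids; areas are pixel-exact within the ROI.
    """
    r0, r1, c0, c1 = roi
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, seg.labels.shape[0]), min(c1, seg.labels.shape[1])
    sub = seg.labels[r0:r1, c0:c1]
    out = {}
    for cls in (LIVE, DEAD):
        rows = seg.cells[seg.cells["viability"] == cls] if seg.n_cells else seg.cells
        in_roi = rows[
            (rows["centroid_row"] >= r0) & (rows["centroid_row"] < r1)
            & (rows["centroid_col"] >= c0) & (rows["centroid_col"] < c1)
        ] if len(rows) else rows
        labels_cls = set(rows["label"]) if len(rows) else set()
        area_px = int(np.isin(sub, list(labels_cls)).sum()) if labels_cls else 0
        out[cls] = (len(in_roi), area_px * seg.pixel_size**2)
    return out


def quantify_viability(
    pre_seg: CellSegmentation,
    post_seg: CellSegmentation,
    alignment: RoiAlignment,
) -> ViabilityResult:
    """Impact-induced death accounting inside the registered overlap ROI."""
    r0, r1, c0, c1 = alignment.roi
    if r1 <= r0 or c1 <= c0:
        raise ValueError("empty overlap ROI between pre and post frames")
    if "viability" not in pre_seg.cells.columns or "viability" not in post_seg.cells.columns:
        raise ValueError("segmentations must be classified (classify_viability) first")

    pre_stats = _roi_class_stats(pre_seg, alignment.roi)
    post_stats = _roi_class_stats(post_seg, alignment.roi_in_post())

    raw = post_stats[DEAD][1] - pre_stats[DEAD][1]
    death_area = max(0.0, raw)
    pre_live_area = pre_stats[LIVE][1]
    frac = death_area / pre_live_area if pre_live_area > 0 else float("nan")
    frac = min(frac, 1.0) if np.isfinite(frac) else frac
    return ViabilityResult(
        pre_live_count=pre_stats[LIVE][0],
        pre_dead_count=pre_stats[DEAD][0],
        post_live_count=post_stats[LIVE][0],
        post_dead_count=post_stats[DEAD][0],
        pre_live_area_um2=pre_stats[LIVE][1],
        pre_dead_area_um2=pre_stats[DEAD][1],
        post_live_area_um2=post_stats[LIVE][1],
        post_dead_area_um2=post_stats[DEAD][1],
        death_area_um2=death_area,
        death_area_raw_um2=float(raw),
        death_area_fraction=frac,
        alignment=alignment,
    )


# --------------------------------------------------------------------------
# end-to-end pair analysis
# --------------------------------------------------------------------------

@dataclass
class ViabilityParams:
    """Tunable parameters of the pair analysis, all in physical units."""

    min_cell_area: float = 20.0      # μm²
    min_separation_um: float = 5.0   # watershed seed separation
    max_shift: int = 50              # px registration search radius
    score_floor: float = 0.2
    tie_class: str = DEAD
    exclusion_mask: np.ndarray | None = None   # True = analyzable region


def _segment_frame(
    stack: MicrographStack, params: ViabilityParams
) -> CellSegmentation:
    live = max_intensity_projection(stack, LIVE)
    dead = max_intensity_projection(stack, DEAD)
    composite = np.maximum(live, dead)
    fg = composite > otsu_threshold(composite)
    if params.exclusion_mask is not None:
        fg &= params.exclusion_mask
    seg = segment_cells(
        fg,
        {LIVE: live, DEAD: dead},
        pixel_size=stack.pixel_size,
        min_cell_area=params.min_cell_area,
        min_separation_um=params.min_separation_um,
    )
    return classify_viability(seg, live, dead, tie_class=params.tie_class)


def analyze_pair(
    pre: MicrographStack,
    post: MicrographStack,
    params: ViabilityParams | None = None,
) -> tuple[ViabilityResult, CellSegmentation, CellSegmentation, RoiAlignment]:
    """Full pre/post pipeline: project, segment, classify, register, quantify."""
    params = params or ViabilityParams()
    pre_seg = _segment_frame(pre, params)
    post_seg = _segment_frame(post, params)
    pre_comp = np.maximum(max_intensity_projection(pre, LIVE),
                          max_intensity_projection(pre, DEAD))
    post_comp = np.maximum(max_intensity_projection(post, LIVE),
                           max_intensity_projection(post, DEAD))
    alignment = register_roi(pre_comp, post_comp,
                             max_shift=params.max_shift,
                             score_floor=params.score_floor)
    result = quantify_viability(pre_seg, post_seg, alignment)
    return result, pre_seg, post_seg, alignment
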
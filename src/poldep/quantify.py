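"""Measurement pipeline: max projection, segmentation, ROI intensities.

Mirrors the screen's measurement procedure on each field of view:

1. maximum projection of the 31-slice z-stack (both channels);
2. segmentation of rod-shaped interphase cells on the GFP projection
   (global robust threshold, morphology clean-up, rod quality gates);
3. genotype calling from the red channel: cells with a punctate
   spindle-pole-body spot are wild-type controls, cells without are
   deletions, with a hysteresis band of ambiguous cells that are
   excluded from statistics;
4. one background ROI per field: a 3 um circular disc placed in the
   cell-free area at the position of minimum local variance;
5. per cell, three 3 um circular ROIs — both cell ends and a cytosol
   disc at the centroid with bright foci excluded — measured as mean and
   max, raw and background-corrected. "End1" is the brighter end.

Where the original measurements were drawn by hand, the segmentation and
ROI placement here are deterministic automated surrogates; every
exclusion carries a QC flag so that segmented = analysed + excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .synthgen import CONTROL, DELETION, FieldStack

AMBIGUOUS = "ambiguous"


class FieldRejectedError(RuntimeError):
    """No usable background ROI (or controls) in this field."""


class MeasurementError(RuntimeError):
    """An ROI could not be measured for this cell."""


@dataclass(frozen=True)
class QuantifyParams:
    """Tunable measurement parameters (lengths in um)."""

    roi_diameter: float = 3.0
    background_clearance: float = 1.0   # disc-to-cell clearance
    threshold_k: float = 6.0            # robust sigmas above the median
    min_cell_area: float = 8.0          # um^2, pre-filter for specks
    length_gate: tuple[float, float] = (5.0, 16.0)
    min_aspect: float = 1.5
    septum_ratio: float = 2.5           # mid-cell band brightness gate
    spot_k_hi: float = 5.0              # control: prominence >= k_hi * bg
    spot_k_lo: float = 2.5              # deletion: prominence < k_lo * bg
    min_roi_in_image: float = 0.8       # allowed border clipping of a disc
    cyto_foci_percentile: float = 90.0  # "non-foci" exclusion rule


@dataclass
class SegmentedCell:
    """A labelled rod candidate on the projected image (pixel coords)."""

    cell_id: str
    bbox: tuple[slice, slice]
    mask: np.ndarray            # local boolean mask within bbox
    centroid: tuple[float, float]   # (row, col) px
    orientation: float              # radians of the principal axis
    length_um: float
    width_um: float
    pole1: tuple[float, float]      # (row, col) px, assigned later by GFP
    pole2: tuple[float, float]
    genotype: str = "unknown"
    qc_flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.qc_flags

    def global_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.bbox] = self.mask
        return out


@dataclass
class CellMeasurement:
    """Background-corrected ROI intensities for one analysed cell."""

    cell_id: str
    field_id: str
    marker: str
    deletion: str
    genotype: str
    end1_mean_raw: float
    end1_max_raw: float
    end2_mean_raw: float
    end2_max_raw: float
    cyto_mean_raw: float
    cyto_max_raw: float
    background_mean: float
    end1_pole: tuple[float, float] = (np.nan, np.nan)
    end2_pole: tuple[float, float] = (np.nan, np.nan)

    @property
    def end1_mean(self) -> float:
        return self.end1_mean_raw - self.background_mean

    @property
    def end1_max(self) -> float:
        return self.end1_max_raw - self.background_mean

    @property
    def end2_mean(self) -> float:
        return self.end2_mean_raw - self.background_mean

    @property
    def end2_max(self) -> float:
        return self.end2_max_raw - self.background_mean

    @property
    def cyto_mean(self) -> float:
        return self.cyto_mean_raw - self.background_mean

    @property
    def cyto_max(self) -> float:
        return self.cyto_max_raw - self.background_mean

    @property
    def bipolarity_index(self) -> float:
        """End2/End1 corrected-mean ratio in [0, 1]; 0 if End1 <= 0."""
        if self.end1_mean <= 0:
            return 0.0
        return float(np.clip(self.end2_mean / self.end1_mean, 0.0, 1.0))


MEASUREMENT_COLUMNS = [
    "field_id", "cell_id", "marker", "deletion", "genotype",
    "end1_mean", "end1_max", "end2_mean", "end2_max",
    "cyto_mean", "cyto_max",
    "end1_mean_raw", "end1_max_raw", "end2_mean_raw", "end2_max_raw",
    "cyto_mean_raw", "cyto_max_raw",
    "background_mean", "bipolarity_index",
    "end1_row", "end1_col", "end2_row", "end2_col",
]


def measurements_to_frame(cells: list[CellMeasurement]) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append({
            "field_id": c.field_id, "cell_id": c.cell_id,
            "marker": c.marker, "deletion": c.deletion,
            "genotype": c.genotype,
            "end1_mean": c.end1_mean, "end1_max": c.end1_max,
            "end2_mean": c.end2_mean, "end2_max": c.end2_max,
            "cyto_mean": c.cyto_mean, "cyto_max": c.cyto_max,
            "end1_mean_raw": c.end1_mean_raw, "end1_max_raw": c.end1_max_raw,
            "end2_mean_raw": c.end2_mean_raw, "end2_max_raw": c.end2_max_raw,
            "cyto_mean_raw": c.cyto_mean_raw, "cyto_max_raw": c.cyto_max_raw,
            "background_mean": c.background_mean,
            "bipolarity_index": c.bipolarity_index,
            "end1_row": c.end1_pole[0], "end1_col": c.end1_pole[1],
            "end2_row": c.end2_pole[0], "end2_col": c.end2_pole[1],
        })
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


# ---------------------------------------------------------------------------
# projection

def max_project(stack: FieldStack | np.ndarray,
                channel: str | None = None) -> np.ndarray:
    """Per-pixel maximum over z. ``channel`` selects 'gfp' or 'red' when a
    :class:`FieldStack` is given."""
    if isinstance(stack, FieldStack):
        if channel not in ("gfp", "red"):
            raise ValueError("channel must be 'gfp' or 'red'")
        arr = getattr(stack, channel)
    else:
        arr = np.asarray(stack)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("expected a non-empty (z, y, x) stack")
    return arr.max(axis=0)


# ---------------------------------------------------------------------------
# segmentation

def _robust_stats(img: np.ndarray) -> tuple[float, float]:
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    return med, 1.4826 * mad


def _principal_axis(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit principal-axis vector (row, col) of a mask."""
    pts = np.argwhere(mask).astype(float)
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts)
    w, v = np.linalg.eigh(cov)
    return c, v[:, np.argmax(w)]


def _septated(proj: np.ndarray, cell: "SegmentedCell", med: float,
              ratio: float) -> bool:
    """Transverse bright ridge at mid-cell marks a septating cell."""
    local = proj[cell.bbox]
    pts = np.argwhere(cell.mask).astype(float)
    c, axis = _principal_axis(cell.mask)
    t = (pts - c) @ axis
    vals = local[cell.mask] - med
    half = t.max()
    if half <= 0:
        return False
    rel = np.abs(t) / half
    mid = vals[rel < 0.12]
    flank = vals[(rel > 0.25) & (rel < 0.55)]
    if len(mid) < 5 or len(flank) < 5:
        return False
    f = np.mean(flank)
    return f > 0 and np.mean(mid) > ratio * f


def _refine_pole(proj_sm: np.ndarray, cell_mask: np.ndarray,
                 bbox: tuple[slice, slice], pole: np.ndarray,
                 radius_px: float, med_global: float) -> np.ndarray:
    """Snap a crude mask-extreme pole onto the local tip-spot maximum.

    Thresholded masks overshoot bright tips (the spot's blurred skirt
    clears the threshold well beyond the cell outline), so when a clear
    local maximum exists near the mask end the pole is moved there; flat
    (cytosol-only) ends keep the geometric extreme."""
    r0, c0 = int(round(pole[0])), int(round(pole[1]))
    H, W = proj_sm.shape
    rr = slice(max(r0 - int(radius_px), 0), min(r0 + int(radius_px) + 1, H))
    cc = slice(max(c0 - int(radius_px), 0), min(c0 + int(radius_px) + 1, W))
    local = proj_sm[rr, cc]
    inmask = np.zeros(proj_sm.shape, bool)
    inmask[bbox] = cell_mask
    sel = inmask[rr, cc]
    if not sel.any():
        return pole
    vals = np.where(sel, local, -np.inf)
    cell_med = float(np.median(proj_sm[inmask]))
    peak = float(vals.max())
    baseline = max(cell_med - med_global, 0.0)
    if peak - cell_med <= baseline:  # no distinct tip spot
        return pole
    k = np.unravel_index(int(np.argmax(vals)), vals.shape)
    return np.array([rr.start + k[0], cc.start + k[1]], dtype=float)


def segment_cells(gfp_projection: np.ndarray, pixel_size: float,
                  params: QuantifyParams = QuantifyParams()
                  ) -> list[SegmentedCell]:
    """Rod candidates on the projection; QC failures are flagged, not
    silently dropped (an empty list is a valid result)."""
    proj = np.asarray(gfp_projection, dtype=np.float32)
    if proj.ndim != 2 or (proj < 0).any():
        raise ValueError("projection must be 2-D and non-negative")
    med, sigma = _robust_stats(proj)
    if sigma > 0:
        thr = med + params.threshold_k * sigma
    else:  # noise-free image: any signal above the flat background
        thr = med + 1e-3 * (float(proj.max()) - med)
    if not np.isfinite(thr) or thr <= med:
        return []
    binary = proj > thr
    binary = ndi.binary_closing(binary, structure=skmorph.disk(1))
    binary = ndi.binary_fill_holes(binary)
    min_px = max(int(params.min_cell_area / pixel_size ** 2), 4)
    labels, _ = ndi.label(binary)
    proj_sm = ndi.gaussian_filter(proj, 1.0)

    cells = []
    H, W = proj.shape
    for region in skmeasure.regionprops(labels):
        if region.area < min_px:
            continue
        sl = region.slice
        mask = labels[sl] == region.label
        c, axis = _principal_axis(mask)
        pts = np.argwhere(mask).astype(float)
        t = (pts - c) @ axis
        off0 = np.array([sl[0].start, sl[1].start], dtype=float)
        refine_r = 1.5 / pixel_size
        p1 = _refine_pole(proj_sm, mask, sl, pts[np.argmax(t)] + off0,
                          refine_r, med) - off0
        p2 = _refine_pole(proj_sm, mask, sl, pts[np.argmin(t)] + off0,
                          refine_r, med) - off0
        length = (t.max() - t.min() + 1.0) * pixel_size
        width = region.axis_minor_length * pixel_size
        off = np.array([sl[0].start, sl[1].start], dtype=float)
        cell = SegmentedCell(
            cell_id=f"r{region.label:03d}",
            bbox=sl, mask=mask,
            centroid=tuple(c + off),
            orientation=float(np.arctan2(axis[0], axis[1])),
            length_um=float(length),
            width_um=float(width),
            pole1=tuple(p1 + off), pole2=tuple(p2 + off),
        )
        # closing erodes edge-touching pixels, so allow 1 px of slack
        if (sl[0].start <= 1 or sl[1].start <= 1
                or sl[0].stop >= H - 1 or sl[1].stop >= W - 1):
            cell.qc_flags.append("border")
        lo, hi = params.length_gate
        if not lo <= cell.length_um <= hi:
            cell.qc_flags.append("length")
        if width > 0 and length / width < params.min_aspect:
            cell.qc_flags.append("non_rod")
        if _septated(proj, cell, med, params.septum_ratio):
            cell.qc_flags.append("septated")
        cells.append(cell)
    return cells


# ---------------------------------------------------------------------------
# genotype calling

def call_genotype(cell: SegmentedCell, red_projection: np.ndarray,
                  params: QuantifyParams = QuantifyParams(),
                  red_stats: tuple[float, float] | None = None) -> str:
    """'control' iff the mask holds a punctate red local maximum with
    prominence >= k_hi x the robust red background; 'deletion' iff the
    brightest in-mask point stays below k_lo x background; 'ambiguous'
    in between (excluded from statistics downstream).

    ``red_stats`` optionally carries precomputed (median, robust sigma)
    of the projection so per-field callers pay for them once."""
    red = np.asarray(red_projection, dtype=np.float32)
    med, sigma = red_stats if red_stats is not None else _robust_stats(red)
    bg = med if med > 0 else max(sigma, 1e-6)
    local = red[cell.bbox]
    vals = local[cell.mask]
    if vals.size == 0:
        return AMBIGUOUS
    idx = int(np.argmax(vals))
    prominence = float(vals[idx] - med)
    # punctate check: the candidate must be a local maximum of the image
    pos = np.argwhere(cell.mask)[idx]
    r0 = cell.bbox[0].start + pos[0]
    c0 = cell.bbox[1].start + pos[1]
    neigh = red[max(r0 - 1, 0): r0 + 2, max(c0 - 1, 0): c0 + 2]
    is_peak = red[r0, c0] >= neigh.max()
    if is_peak and prominence >= params.spot_k_hi * bg:
        return CONTROL
    if prominence < params.spot_k_lo * bg:
        return DELETION
    return AMBIGUOUS


# ---------------------------------------------------------------------------
# background and ROI measurement

def _disc_offsets(radius_px: int) -> np.ndarray:
    r = radius_px
    dy, dx = np.mgrid[-r: r + 1, -r: r + 1]
    return np.argwhere(dy ** 2 + dx ** 2 <= r ** 2) - r


def roi_radius_px(pixel_size: float, roi_diameter: float = 3.0) -> int:
    """3 um diameter converted to an integer pixel radius (nearest px)."""
    return max(int(round(roi_diameter / 2.0 / pixel_size)), 1)


def _disc_values(img: np.ndarray, center: tuple[float, float],
                 radius_px: int) -> np.ndarray:
    r0, c0 = int(round(center[0])), int(round(center[1]))
    off = _disc_offsets(radius_px)
    rr, cc = off[:, 0] + r0, off[:, 1] + c0
    keep = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
    frac = keep.mean()
    return img[rr[keep], cc[keep]], frac


def estimate_background(gfp_projection: np.ndarray,
                        cell_masks: list[SegmentedCell] | np.ndarray,
                        pixel_size: float,
                        params: QuantifyParams = QuantifyParams()) -> float:
    """Mean of one 3 um background disc.

    Candidate centres keep the whole disc >= ``background_clearance`` um
    from every cell mask and fully inside the image; among candidates the
    disc with the smallest intensity variance is chosen (deterministic:
    first in row-major order on ties), so isolated debris is avoided.
    """
    proj = np.asarray(gfp_projection, dtype=np.float64)
    if isinstance(cell_masks, np.ndarray):
        union = cell_masks.astype(bool)
    else:
        union = np.zeros(proj.shape, dtype=bool)
        for cell in cell_masks:
            union[cell.bbox] |= cell.mask
    r = roi_radius_px(pixel_size, params.roi_diameter)
    clearance_px = params.background_clearance / pixel_size
    dist = ndi.distance_transform_edt(~union)
    valid = dist >= (r + clearance_px)
    valid[:r, :] = valid[-r:, :] = False
    valid[:, :r] = valid[:, -r:] = False
    if not valid.any():
        raise FieldRejectedError("no cell-free background ROI available")

    footprint = (np.add.outer(np.arange(-r, r + 1) ** 2,
                              np.arange(-r, r + 1) ** 2) <= r ** 2)
    area = footprint.sum()
    s1 = ndi.correlate(proj, footprint.astype(np.float64), mode="constant")
    s2 = ndi.correlate(proj ** 2, footprint.astype(np.float64),
                       mode="constant")
    mean = s1 / area
    var = np.maximum(s2 / area - mean ** 2, 0.0)
    var_masked = np.where(valid, var, np.inf)
    idx = np.unravel_index(int(np.argmin(var_masked)), var_masked.shape)
    return float(mean[idx])


def measure_cell(cell: SegmentedCell, gfp_projection: np.ndarray,
                 background_mean: float, pixel_size: float,
                 marker: str = "", deletion: str = "", field_id: str = "",
                 params: QuantifyParams = QuantifyParams()
                 ) -> CellMeasurement:
    """Three 3 um ROIs (pole1, pole2, centroid-cytosol) on the projection.

    Cytosol pixels above the disc's ``cyto_foci_percentile`` are dropped
    before averaging (the "non-foci" rule). End1/End2 are assigned so the
    background-corrected End1 mean is the larger; the assignment is
    intensity-based, never annotation-order-based.
    """
    proj = np.asarray(gfp_projection, dtype=np.float64)
    r = roi_radius_px(pixel_size, params.roi_diameter)
    rois = {}
    for name, center in (("p1", cell.pole1), ("p2", cell.pole2),
                         ("cyto", cell.centroid)):
        vals, frac = _disc_values(proj, center, r)
        if vals.size == 0:
            raise MeasurementError(f"ROI {name} entirely outside the image")
        if frac < params.min_roi_in_image:
            raise MeasurementError(f"ROI {name} clipped below "
                                   f"{params.min_roi_in_image:.0%} in-image")
        rois[name] = vals
    cyto = rois["cyto"]
    cut = np.percentile(cyto, params.cyto_foci_percentile)
    non_foci = cyto[cyto <= cut]
    if non_foci.size == 0:
        non_foci = cyto

    stats = {n: (float(v.mean()), float(v.max()))
             for n, v in (("p1", rois["p1"]), ("p2", rois["p2"]))}
    if (stats["p1"][0] - background_mean) >= (stats["p2"][0]
                                              - background_mean):
        first, second = "p1", "p2"
        e1_pole, e2_pole = cell.pole1, cell.pole2
    else:
        first, second = "p2", "p1"
        e1_pole, e2_pole = cell.pole2, cell.pole1
    return CellMeasurement(
        cell_id=cell.cell_id, field_id=field_id,
        marker=marker, deletion=deletion, genotype=cell.genotype,
        end1_mean_raw=stats[first][0], end1_max_raw=stats[first][1],
        end2_mean_raw=stats[second][0], end2_max_raw=stats[second][1],
        cyto_mean_raw=float(non_foci.mean()),
        cyto_max_raw=float(non_foci.max()),
        background_mean=float(background_mean),
        end1_pole=e1_pole, end2_pole=e2_pole,
    )


def match_to_annotations(measurements: pd.DataFrame,
                         annotations: pd.DataFrame,
                         pixel_size: float,
                         max_dist: float = 2.0) -> pd.DataFrame:
    """Join measured cells to ground-truth annotations by position.

    Segmentation assigns its own cell ids, so measured cells are matched
    to the nearest annotated cell (midpoint of the measured poles vs the
    annotated cell centre, both in um) within ``max_dist``. Ground-truth
    columns gain a ``true_`` / ``_ann`` naming."""
    rows = []
    for field_id, grp in measurements.groupby("field_id", sort=False):
        ann = annotations[annotations["field_id"] == field_id]
        if ann.empty:
            continue
        ax = (ann["pole1_x"] + ann["pole2_x"]).to_numpy() / 2.0
        ay = (ann["pole1_y"] + ann["pole2_y"]).to_numpy() / 2.0
        for _, m in grp.iterrows():
            mx = (m["end1_col"] + m["end2_col"] + 1.0) / 2.0 * pixel_size
            my = (m["end1_row"] + m["end2_row"] + 1.0) / 2.0 * pixel_size
            d = np.hypot(ax - mx, ay - my)
            j = int(np.argmin(d))
            if d[j] > max_dist:
                continue
            row = dict(m)
            a = ann.iloc[j]
            row.update({
                "genotype_true": a["genotype"],
                "true_end1": a["true_end1"], "true_end2": a["true_end2"],
                "true_cyto": a["true_cyto"],
                "pole1_x": a["pole1_x"], "pole1_y": a["pole1_y"],
                "pole2_x": a["pole2_x"], "pole2_y": a["pole2_y"],
                "match_dist": float(d[j]),
            })
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-field driver

@dataclass
class FieldQuantification:
    field_id: str
    measurements: list[CellMeasurement]
    cells: list[SegmentedCell]
    background_mean: float
    n_segmented: int = 0
    n_analysed: int = 0
    n_excluded: int = 0


def quantify_field(stack: FieldStack,
                   params: QuantifyParams = QuantifyParams()
                   ) -> FieldQuantification:
    """Run the full measurement procedure on one field."""
    gfp = max_project(stack, "gfp")
    red = max_project(stack, "red")
    ps = stack.pixel_size_xy
    cells = segment_cells(gfp, ps, params)
    background = estimate_background(gfp, cells, ps, params)
    red_stats = _robust_stats(np.asarray(red, dtype=np.float32))
    measurements = []
    for cell in cells:
        cell.cell_id = f"{stack.field_id}:{cell.cell_id}"
        cell.genotype = call_genotype(cell, red, params, red_stats=red_stats)
        if cell.genotype == AMBIGUOUS:
            cell.qc_flags.append("ambiguous_genotype")
        if not cell.ok:
            continue
        try:
            m = measure_cell(cell, gfp, background, ps,
                             marker=stack.marker, deletion=stack.deletion,
                             field_id=stack.field_id, params=params)
        except MeasurementError:
            cell.qc_flags.append("roi_clipped")
            continue
        measurements.append(m)
    n_seg = len(cells)
    n_ok = len(measurements)
    return FieldQuantification(
        field_id=stack.field_id, measurements=measurements, cells=cells,
        background_mean=background, n_segmented=n_seg, n_analysed=n_ok,
        n_excluded=n_seg - n_ok)
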
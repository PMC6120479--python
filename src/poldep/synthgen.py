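"""Synthetic two-channel z-stack generator for mixed-genotype fields.

Emulates the imaging design of an internally-controlled polarity screen:
each field of view contains rod-shaped fission-yeast cells of two
genotypes imaged in two channels —

* **GFP channel**: the polarity marker, rendered as a uniform cytosolic
  plateau inside the rod mask plus Gaussian spots at the two cell tips;
* **red channel**: wild-type (control) cells carry one or two bright
  punctate spindle-pole-body spots, deletion cells carry none.

Signal is distributed over 31 z-slices through a Gaussian axial
focus/thickness profile whose peak (value 1) sits at the cell mid-plane,
so the noise-free maximum projection recovers the in-focus column image.
The lateral PSF is folded analytically into each cell's contribution
(blurred rod mask, variance-added tip Gaussians), which is equivalent to
blurring each summed slice because convolution is linear. Shot noise
(Poisson), Gaussian read noise and a constant camera background are then
applied per voxel; each term can be switched off independently.

Ground-truth effects enter purely phenomenologically: deletion cells'
tip/cytosol amplitudes are scaled by the multipliers of a
:class:`~poldep.design.GroundTruthEffect` and their bipolarity parameter
is shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .design import GroundTruthEffect, StudyDesign, truth_lookup

CONTROL = "control"
DELETION = "deletion"


class PlacementError(RuntimeError):
    """A cell could not be placed without overlap (or outside the canvas)."""


class CapacityError(RuntimeError):
    """The field is too small for the requested number of cells."""


@dataclass(frozen=True)
class FieldParams:
    """Geometry of a field of view / stack."""

    shape: tuple[int, int] = (256, 256)  # (rows, cols) px
    pixel_size_xy: float = 0.1  # um/px
    n_z: int = 31
    z_step: float = 0.2  # um

    @property
    def z_mid(self) -> float:
        """Focal mid-plane (um), centre slice of the stack."""
        return (self.n_z // 2) * self.z_step


@dataclass(frozen=True)
class NoiseParams:
    """Widefield noise model; set a term to 0 to switch it off."""

    psf_sigma: float = 0.15       # lateral PSF sigma, um
    poisson_scale: float = 1.0    # shot-noise gain (0 disables)
    read_sigma: float = 2.0       # additive Gaussian read noise, counts
    background_offset: float = 100.0  # constant camera offset, counts

    @classmethod
    def noiseless(cls, psf_sigma: float = 0.0,
                  background_offset: float = 0.0) -> "NoiseParams":
        return cls(psf_sigma=psf_sigma, poisson_scale=0.0, read_sigma=0.0,
                   background_offset=background_offset)


@dataclass(frozen=True)
class CellModel:
    """Baseline cell geometry and brightness priors.

    Densities are photon column densities (photons/um^2): tip and SPB
    values are rendered Gaussian *peak* densities, the cytosol value a
    plateau. ``bipolarity_mean`` is the mean End2/End1 amplitude ratio of
    an unperturbed interphase population (monopolar-leaning).
    """

    length_range: tuple[float, float] = (7.0, 14.0)  # um
    width: float = 3.5  # um
    tip_peak_density: float = 250_000.0
    cyto_density: float = 3_000.0
    spb_peak_density: float = 150_000.0
    bipolarity_mean: float = 0.30
    bipolarity_sd: float = 0.10
    expression_cv: float = 0.15
    tip_sigma: float = 0.20      # intrinsic lateral tip-spot sigma, um
    tip_sigma_z: float = 0.50    # axial tip profile sigma, um
    cyto_sigma_z: float = 0.90   # axial cytosol profile sigma, um
    spb_sigma: float = 0.15      # intrinsic lateral SPB sigma, um
    spb_sigma_z: float = 0.40
    two_spot_prob: float = 0.30  # pre-mitotic cells carry two SPB dots
    min_spacing: float = 1.8     # um clearance between cell masks
    margin: float = 1.0          # um clearance from the field border
    max_attempts: int = 500


@dataclass(frozen=True)
class CellGeometry:
    """A rod (spherocylinder) in field coordinates (um)."""

    center: tuple[float, float]  # (x, y)
    orientation: float           # radians
    length: float                # um, pole to pole
    width: float = 3.5

    def __post_init__(self):
        if self.length <= self.width:
            raise ValueError("length must exceed width")

    @property
    def pole1(self) -> tuple[float, float]:
        cx, cy = self.center
        h = self.length / 2.0
        return (cx + h * np.cos(self.orientation),
                cy + h * np.sin(self.orientation))

    @property
    def pole2(self) -> tuple[float, float]:
        cx, cy = self.center
        h = self.length / 2.0
        return (cx - h * np.cos(self.orientation),
                cy - h * np.sin(self.orientation))


@dataclass
class CellAnnotation:
    """Ground truth stored with every rendered cell."""

    cell_id: str
    genotype: str
    marker: str
    deletion: str
    geometry: CellGeometry
    pole1: tuple[float, float]  # brighter pole (um)
    pole2: tuple[float, float]
    true_end1: float            # effective peak density of brighter tip
    true_end2: float
    true_cyto: float
    bipolarity: float
    n_spb_spots: int


@dataclass
class FieldStack:
    """One two-channel z-stack plus its ground-truth annotations."""

    gfp: np.ndarray  # (z, y, x) float32
    red: np.ndarray
    pixel_size_xy: float
    z_step: float
    field_id: str
    marker: str = ""
    deletion: str = ""
    annotations: list[CellAnnotation] = field(default_factory=list)
    expected_total_gfp: float = 0.0  # analytic noise-free photon sum

    def __post_init__(self):
        if self.gfp.shape != self.red.shape:
            raise ValueError("channel shapes differ")
        if self.gfp.ndim != 3:
            raise ValueError("stacks must be (z, y, x)")

    @property
    def n_z(self) -> int:
        return self.gfp.shape[0]

    def annotation_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.annotations:
            rows.append({
                "field_id": self.field_id,
                "cell_id": a.cell_id,
                "genotype": a.genotype,
                "marker": a.marker,
                "deletion": a.deletion,
                "pole1_x": a.pole1[0], "pole1_y": a.pole1[1],
                "pole2_x": a.pole2[0], "pole2_y": a.pole2[1],
                "true_end1": a.true_end1,
                "true_end2": a.true_end2,
                "true_cyto": a.true_cyto,
            })
        cols = ["field_id", "cell_id", "genotype", "marker", "deletion",
                "pole1_x", "pole1_y", "pole2_x", "pole2_y",
                "true_end1", "true_end2", "true_cyto"]
        return pd.DataFrame(rows, columns=cols)


def empty_field(params: FieldParams, field_id: str = "field",
                marker: str = "", deletion: str = "") -> FieldStack:
    shape = (params.n_z, *params.shape)
    return FieldStack(
        gfp=np.zeros(shape, np.float32),
        red=np.zeros(shape, np.float32),
        pixel_size_xy=params.pixel_size_xy,
        z_step=params.z_step,
        field_id=field_id,
        marker=marker,
        deletion=deletion,
    )


# ---------------------------------------------------------------------------
# geometry rasterisation

def rod_mask_bbox(geom: CellGeometry, shape: tuple[int, int],
                  pixel_size: float, pad_um: float = 0.0,
                  inflate_um: float = 0.0):
    """Rasterise a rod as (bbox slices, local boolean mask).

    ``inflate_um`` grows the rod radius (used for spacing checks);
    ``pad_um`` grows only the bounding box (used to leave room for blur).
    """
    ps = pixel_size
    r = geom.width / 2.0 + inflate_um
    cx, cy = geom.center
    h = geom.length / 2.0 - geom.width / 2.0  # inner segment half-length
    ux, uy = np.cos(geom.orientation), np.sin(geom.orientation)
    ax, ay = cx - h * ux, cy - h * uy
    bx, by = cx + h * ux, cy + h * uy

    extent = h + r + pad_um
    x_lo = int(np.floor((cx - extent) / ps))
    x_hi = int(np.ceil((cx + extent) / ps)) + 1
    y_lo = int(np.floor((cy - extent) / ps))
    y_hi = int(np.ceil((cy + extent) / ps)) + 1
    y_lo, y_hi = max(y_lo, 0), min(y_hi, shape[0])
    x_lo, x_hi = max(x_lo, 0), min(x_hi, shape[1])
    if y_lo >= y_hi or x_lo >= x_hi:
        raise PlacementError("cell lies outside the canvas")

    ys = (np.arange(y_lo, y_hi) + 0.5) * ps
    xs = (np.arange(x_lo, x_hi) + 0.5) * ps
    X, Y = np.meshgrid(xs, ys)
    # distance from pixel centres to the rod axis segment
    px, py = X - ax, Y - ay
    sx, sy = bx - ax, by - ay
    seg2 = sx * sx + sy * sy
    t = np.clip((px * sx + py * sy) / max(seg2, 1e-12), 0.0, 1.0)
    dx, dy = px - t * sx, py - t * sy
    mask = dx * dx + dy * dy <= r * r
    return (slice(y_lo, y_hi), slice(x_lo, x_hi)), mask


def _axial_profile(params: FieldParams, sigma_z: float,
                   z_center: float | None = None) -> np.ndarray:
    z = np.arange(params.n_z) * params.z_step
    zc = params.z_mid if z_center is None else z_center
    return np.exp(-0.5 * ((z - zc) / sigma_z) ** 2).astype(np.float32)


def _add_gaussian_spot(channel: np.ndarray, center_um: tuple[float, float],
                       peak: float, sigma_um: float, axial: np.ndarray,
                       pixel_size: float) -> float:
    """Add a lateral-Gaussian, axially-profiled spot; return its analytic
    photon integral over the (continuous-xy, discrete-z) grid."""
    ps = pixel_size
    s_px = sigma_um / ps
    cx, cy = center_um[0] / ps - 0.5, center_um[1] / ps - 0.5  # px centres
    half = int(np.ceil(4.5 * s_px)) + 1
    y_lo = max(int(np.floor(cy)) - half, 0)
    y_hi = min(int(np.ceil(cy)) + half + 1, channel.shape[1])
    x_lo = max(int(np.floor(cx)) - half, 0)
    x_hi = min(int(np.ceil(cx)) + half + 1, channel.shape[2])
    if y_lo >= y_hi or x_lo >= x_hi:
        return 0.0
    ys = np.arange(y_lo, y_hi, dtype=np.float32)
    xs = np.arange(x_lo, x_hi, dtype=np.float32)
    g = np.exp(-0.5 * (((ys[:, None] - cy) ** 2 +
                        (xs[None, :] - cx) ** 2) / s_px ** 2))
    channel[:, y_lo:y_hi, x_lo:x_hi] += (
        peak * axial[:, None, None] * g[None, :, :])
    return float(peak * 2.0 * np.pi * s_px ** 2 * axial.sum())


def render_cell(
    geom: CellGeometry,
    genotype: str,
    tip1_amp: float,
    tip2_amp: float,
    cyto_amp: float,
    canvas: FieldStack,
    rng: np.random.Generator,
    noise: NoiseParams = NoiseParams(),
    model: CellModel = CellModel(),
    params: FieldParams | None = None,
) -> float:
    """Render one noise-free cell into ``canvas`` (both channels).

    Amplitudes are photon column densities (photons/um^2): ``tip*_amp``
    Gaussian peaks at the two poles, ``cyto_amp`` the plateau inside the
    rod. Control cells additionally get 1-2 red SPB spots. Returns
    ``(gfp_integral, n_spb_spots)`` where the integral is the analytic
    noise-free GFP photon sum of this cell (for conservation checks).
    """
    if genotype not in (CONTROL, DELETION):
        raise ValueError(f"unknown genotype {genotype!r}")
    if min(tip1_amp, tip2_amp, cyto_amp) < 0:
        raise ValueError("amplitudes must be >= 0")
    if params is None:
        params = FieldParams(shape=canvas.gfp.shape[1:],
                             pixel_size_xy=canvas.pixel_size_xy,
                             n_z=canvas.n_z, z_step=canvas.z_step)
    ps = params.pixel_size_xy
    psf_px = noise.psf_sigma / ps

    # cytosolic plateau: PSF-blurred rod mask, shared across z
    pad = 4.0 * noise.psf_sigma + ps
    (sy, sx), mask = rod_mask_bbox(geom, params.shape, ps, pad_um=pad)
    soft = mask.astype(np.float32)
    if psf_px > 0:
        soft = ndi.gaussian_filter(soft, psf_px, mode="constant")
    ax_cyto = _axial_profile(params, model.cyto_sigma_z)
    cyto_px = cyto_amp * ps ** 2
    canvas.gfp[:, sy, sx] += cyto_px * ax_cyto[:, None, None] * soft[None]
    total = float(cyto_px * mask.sum() * ax_cyto.sum())

    # tip spots, PSF folded in analytically
    tip_sigma = float(np.hypot(model.tip_sigma, noise.psf_sigma))
    ax_tip = _axial_profile(params, model.tip_sigma_z)
    for pole, amp in ((geom.pole1, tip1_amp), (geom.pole2, tip2_amp)):
        if amp > 0:
            total += _add_gaussian_spot(canvas.gfp, pole, amp * ps ** 2,
                                        tip_sigma, ax_tip, ps)

    # red genotype tag: SPB dots in controls only
    n_spots = 0
    if genotype == CONTROL:
        n_spots = 2 if rng.random() < model.two_spot_prob else 1
        spb_sigma = float(np.hypot(model.spb_sigma, noise.psf_sigma))
        cx, cy = geom.center
        ux, uy = np.cos(geom.orientation), np.sin(geom.orientation)
        nx, ny = -uy, ux
        for _ in range(n_spots):
            along = rng.uniform(-0.2, 0.2) * geom.length
            across = rng.uniform(-0.25, 0.25) * geom.width
            pos = (cx + along * ux + across * nx,
                   cy + along * uy + across * ny)
            zc = params.z_mid + rng.normal(0.0, 0.15)
            ax_spb = _axial_profile(params, model.spb_sigma_z, z_center=zc)
            _add_gaussian_spot(canvas.red, pos, model.spb_peak_density
                               * ps ** 2, spb_sigma, ax_spb, ps)
    return total, n_spots


def apply_noise(stack: FieldStack, noise: NoiseParams,
                rng: np.random.Generator) -> None:
    """Poisson shot noise, then Gaussian read noise, then constant offset."""
    for channel in (stack.gfp, stack.red):
        if noise.poisson_scale > 0:
            hot = channel > 0
            lam = channel[hot] * noise.poisson_scale
            channel[hot] = rng.poisson(lam) / noise.poisson_scale
        if noise.read_sigma > 0:
            channel += noise.read_sigma * rng.standard_normal(
                channel.shape, dtype=np.float32)
        if noise.background_offset:
            channel += noise.background_offset
        np.clip(channel, 0.0, None, out=channel)


def _draw_geometry(params: FieldParams, model: CellModel,
                   rng: np.random.Generator) -> CellGeometry:
    ps = params.pixel_size_xy
    length = rng.uniform(*model.length_range)
    theta = rng.uniform(0.0, np.pi)
    h = length / 2.0
    # bounding half-extents so the whole rod stays inside the margins
    ex = abs(h * np.cos(theta)) + model.width / 2.0
    ey = abs(h * np.sin(theta)) + model.width / 2.0
    x_max = params.shape[1] * ps - model.margin - ex
    y_max = params.shape[0] * ps - model.margin - ey
    if x_max <= model.margin + ex or y_max <= model.margin + ey:
        raise CapacityError("field too small for a cell of this length")
    cx = rng.uniform(model.margin + ex, x_max)
    cy = rng.uniform(model.margin + ey, y_max)
    return CellGeometry((cx, cy), theta, length, model.width)


def render_field(
    marker: str,
    deletion: str,
    n_control: int,
    n_deletion: int,
    truth: GroundTruthEffect | None = None,
    noise: NoiseParams = NoiseParams(),
    model: CellModel = CellModel(),
    params: FieldParams = FieldParams(),
    seed: int | np.random.Generator = 0,
    field_id: str = "field-0",
) -> FieldStack:
    """Render one mixed field: ``n_control`` wild-type + ``n_deletion``
    deletion cells placed without overlap, then noise applied."""
    if n_control < 1 or n_deletion < 1:
        raise ValueError("each field needs at least one cell per genotype")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if truth is None:
        truth = GroundTruthEffect(marker, deletion)
    stack = empty_field(params, field_id, marker, deletion)
    occupancy = np.zeros(params.shape, dtype=bool)

    genotypes = [CONTROL] * n_control + [DELETION] * n_deletion
    rng.shuffle(genotypes)
    total_gfp = 0.0
    for i, genotype in enumerate(genotypes):
        geom = None
        for _ in range(model.max_attempts):
            cand = _draw_geometry(params, model, rng)
            bbox, infl = rod_mask_bbox(cand, params.shape,
                                       params.pixel_size_xy,
                                       inflate_um=model.min_spacing)
            if not (occupancy[bbox] & infl).any():
                geom = cand
                occupancy[bbox] |= infl
                break
        if geom is None:
            raise PlacementError(
                f"could not place cell {i} after {model.max_attempts} "
                f"attempts in {field_id}")

        expr = rng.lognormal(
            -0.5 * np.log1p(model.expression_cv ** 2),
            np.sqrt(np.log1p(model.expression_cv ** 2)))
        if genotype == DELETION:
            b_mean = model.bipolarity_mean + truth.bipolarity_shift
            m1, m2, mc = truth.mult_end1, truth.mult_end2, truth.mult_cyto
        else:
            b_mean = model.bipolarity_mean
            m1 = m2 = mc = 1.0
        b_cell = float(np.clip(rng.normal(b_mean, model.bipolarity_sd),
                               0.02, 0.98))
        tip_bright = model.tip_peak_density * expr
        tip_a = tip_bright * m1          # nominal brighter tip
        tip_b = tip_bright * b_cell * m2
        cyto = model.cyto_density * expr * mc
        # randomise which geometric pole carries the brighter tip
        if rng.random() < 0.5:
            amp1, amp2 = tip_a, tip_b
        else:
            amp1, amp2 = tip_b, tip_a
        cell_gfp, n_spots = render_cell(
            geom, genotype, amp1, amp2, cyto, stack, rng,
            noise=noise, model=model, params=params)
        total_gfp += cell_gfp
        if amp1 >= amp2:
            bright, dim = geom.pole1, geom.pole2
        else:
            bright, dim = geom.pole2, geom.pole1
        stack.annotations.append(CellAnnotation(
            cell_id=f"{field_id}:c{i:03d}",
            genotype=genotype, marker=marker, deletion=deletion,
            geometry=geom, pole1=bright, pole2=dim,
            true_end1=max(tip_a, tip_b), true_end2=min(tip_a, tip_b),
            true_cyto=cyto, bipolarity=b_cell,
            n_spb_spots=n_spots,
        ))
    stack.expected_total_gfp = total_gfp
    apply_noise(stack, noise, rng)
    return stack


# ---------------------------------------------------------------------------
# study generation / TIFF output

def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def write_stack(stack: FieldStack, path: Path) -> None:
    """Write a field as a multi-page TIFF, channel-major then z
    (pages 0..nz-1 = GFP, nz..2nz-1 = red), uint16."""
    pages = np.concatenate([stack.gfp, stack.red], axis=0)
    arr = np.clip(np.rint(pages), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr,
                     resolution=(1.0 / stack.pixel_size_xy,
                                 1.0 / stack.pixel_size_xy))


def read_stack(path: Path, pixel_size_xy: float, z_step: float,
               field_id: str, marker: str = "",
               deletion: str = "") -> FieldStack:
    pages = tifffile.imread(path).astype(np.float32)
    nz = pages.shape[0] // 2
    return FieldStack(gfp=pages[:nz], red=pages[nz:],
                      pixel_size_xy=pixel_size_xy, z_step=z_step,
                      field_id=field_id, marker=marker, deletion=deletion)


def iter_study_fields(
    design: StudyDesign,
    truth_table: list[GroundTruthEffect],
    noise: NoiseParams = NoiseParams(),
    model: CellModel = CellModel(),
    params: FieldParams = FieldParams(),
    seed: int = 0,
):
    """Yield every field of a study, lazily (one stack in memory at a time).

    Randomness is hierarchical: each field derives its generator from
    (seed, combination index, field index), so any field is reproducible
    in isolation.
    """
    truth = truth_lookup(truth_table)
    for ci, (marker, del_gene) in enumerate(design.combinations):
        eff = truth.get((marker, del_gene),
                        GroundTruthEffect(marker, del_gene))
        counts = _split_counts(design.cells_per_arm,
                               design.fields_per_combination)
        for fi in range(design.fields_per_combination):
            if counts[fi] == 0:
                continue
            fid = f"{marker}_{del_gene}_f{fi:02d}"
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, ci, fi]))
            yield render_field(marker, del_gene, counts[fi], counts[fi],
                               truth=eff, noise=noise, model=model,
                               params=params, seed=rng, field_id=fid)


def generate_study(
    design: StudyDesign,
    truth_table: list[GroundTruthEffect],
    noise: NoiseParams,
    out_dir: str | Path,
    seed: int = 0,
    model: CellModel = CellModel(),
    params: FieldParams = FieldParams(),
) -> pd.DataFrame:
    """Render a whole study to ``out_dir`` (TIFF stacks + CSV sidecars).

    Returns the manifest: one row per field with combination labels and
    the stack filename. Also writes ``annotations.csv`` (ground truth per
    cell) and ``manifest.csv``. Fully reproducible from (design, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows, ann_frames = [], []
    seen = set()
    for stack in iter_study_fields(design, truth_table, noise=noise,
                                   model=model, params=params, seed=seed):
        if stack.field_id in seen:
            raise ValueError(f"duplicate field_id {stack.field_id}")
        seen.add(stack.field_id)
        fname = f"{stack.field_id}.tif"
        write_stack(stack, out / fname)
        n_ctrl = sum(a.genotype == CONTROL for a in stack.annotations)
        manifest_rows.append({
            "field_id": stack.field_id, "marker": stack.marker,
            "deletion": stack.deletion, "path": fname,
            "n_control": n_ctrl,
            "n_deletion": len(stack.annotations) - n_ctrl,
            "pixel_size_xy": stack.pixel_size_xy, "z_step": stack.z_step,
        })
        ann_frames.append(stack.annotation_frame())
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.concat(ann_frames, ignore_index=True).to_csv(
        out / "annotations.csv", index=False)
    return manifest
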
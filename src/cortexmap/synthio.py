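"""Synthetic cortical ribbon phantoms with known cytoarchitecture.

Generates 2D cell-body-stained histology-style images of a cortical ribbon
made of one or more adjacent areas, each with its own laminar pattern
(layer thicknesses, cell densities, cell sizes, stain darkness, columnar
clustering).  Every phantom carries full ground truth: per-pixel layer and
area labels, the binary cell mask, the two cortical boundary contours
(layer I/II interface and grey/white-matter interface) and the arc-length
positions of the true area borders on the outer contour.

Two presets emulate the laminar contrast between primary and secondary
visual cortex: an "hOc1-like" area with sublayers IVa/IVb/IVc (IVc the
densest layer of all, layer V the sparsest of II-VI) and an "hOc2-like"
area with a single thinner layer IV, a pyramidal-cell size gradient in
layer III and stronger columnar arrangement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "LayerSpec",
    "AreaProfile",
    "RenderConfig",
    "CorticalPhantom",
    "make_preset_profile",
    "render_phantom",
    "save_phantom",
    "load_phantom",
    "BACKGROUND_LABEL",
    "WHITE_MATTER_LABEL",
]

BACKGROUND_LABEL = 0
WHITE_MATTER_LABEL = 1
_FIRST_AREA_LABEL = 2

# Greyscale conventions: dark cells on light tissue, tissue slightly darker
# than the slide background, white matter darker still so the four classes
# (background / white matter / two areas) are separable by a segmenter.
BACKGROUND_GREY = 235
CORTEX_GREY = 226
WM_GREY = 214


@dataclass(frozen=True)
class LayerSpec:
    """One cortical layer of an area.

    thickness_fraction is the fraction of the full cortical depth (pia to
    white matter) occupied by the layer; fractions of one area must sum to 1.
    cell_density is the expected number of cell bodies per mm^2;
    cell_radius_mean/sd are in micrometres; stain_intensity is the greyscale
    value the cell bodies are drawn with (0 = black).
    """

    name: str
    thickness_fraction: float
    cell_density: float
    cell_radius_mean: float
    cell_radius_sd: float
    stain_intensity: int = 45
    # optional linear radius gradient across the layer's own depth:
    # radius_mean at the top and bottom edge of the layer (pyramidal-cell
    # size gradient); when None the constant cell_radius_mean is used.
    radius_gradient: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.thickness_fraction < 0:
            raise ValueError(f"layer {self.name}: negative thickness fraction")
        if self.cell_density < 0:
            raise ValueError(f"layer {self.name}: negative cell density")
        if self.cell_radius_mean < 0 or self.cell_radius_sd < 0:
            raise ValueError(f"layer {self.name}: negative radius parameter")


@dataclass(frozen=True)
class AreaProfile:
    """Ordered laminar specification of one cortical area.

    Layers are listed from the pial surface downward.  columnarity in [0, 1]
    modulates the cell point process with a vertical stripe pattern
    (period ~50 um) to mimic columnar arrangement.
    """

    area_id: str
    layers: tuple[LayerSpec, ...]
    columnarity: float = 0.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("an area needs at least one layer")
        total = sum(l.thickness_fraction for l in self.layers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"area {self.area_id}: layer thickness fractions sum to "
                f"{total!r}, expected 1"
            )
        if not 0.0 <= self.columnarity <= 1.0:
            raise ValueError("columnarity must lie in [0, 1]")

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.layers)


@dataclass(frozen=True)
class RenderConfig:
    """Rendering geometry and noise settings.

    resolution_um_per_px: physical pixel size.  geometry "flat" renders the
    ribbon as a horizontal band, "arc" as an annulus sector (curved cortex).
    seed fixes every random draw of the renderer.
    """

    resolution_um_per_px: float = 2.0
    width_px: int = 512
    height_px: int = 512
    cortical_thickness_um: float = 1500.0
    geometry: str = "flat"
    noise_sd: float = 4.0
    layer1_fraction_margin: float = 0.0  # reserved
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution must be positive")
        if self.geometry not in ("flat", "arc"):
            raise ValueError("geometry must be 'flat' or 'arc'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class CorticalPhantom:
    """A rendered phantom with full ground truth."""

    image: np.ndarray  # uint8, HxW
    cell_mask: np.ndarray  # bool, HxW
    layer_labels: np.ndarray  # uint16, 0 = not cortex, 1.. = layer index
    area_labels: np.ndarray  # uint16, 0 bg, 1 wm, 2.. = areas
    outer_contour: np.ndarray  # (N, 2) float, (row, col), layer I/II interface
    inner_contour: np.ndarray  # (N, 2) float, GM/WM interface
    true_border_um: list[float]  # arc-length of area borders on outer contour
    config: RenderConfig
    profiles: tuple[AreaProfile, ...] = field(default_factory=tuple)
    layer_names: dict[int, str] = field(default_factory=dict)

    @property
    def area_ids(self) -> list[int]:
        return [_FIRST_AREA_LABEL + i for i in range(len(self.profiles))]

    def cortex_mask(self) -> np.ndarray:
        return self.area_labels >= _FIRST_AREA_LABEL


# ---------------------------------------------------------------------------
# presets

def make_preset_profile(kind: str) -> AreaProfile:
    """Return one of the built-in area presets.

    "hOc1-like": striate-cortex-like pattern with sublayers IVa/IVb/IVc,
    IVc strictly the densest of all layers and V strictly the sparsest of
    II-VI.  "hOc2-like": extrastriate-like pattern with a single, thinner
    layer IV, a pyramidal-cell size gradient in layer III (larger cells at
    the lower edge) and stronger columnarity.
    """
    # Densities are visible cell bodies per mm^2 in a 20-um-thick cell-body
    # stained section; granular visual cortex is among the densest human
    # cortex, so the granular layers sit in the few-thousands and the
    # resulting GLI amplitudes land in the 0.2-0.4 range typical of the
    # method's literature.
    # The primary area carries roughly twice the neuronal density of its
    # neighbour (the classical V1/V2 contrast), concentrated in the granular
    # sublayers.
    if kind == "hOc1-like":
        layers = (
            LayerSpec("I", 0.10, 500.0, 4.0, 0.8),
            LayerSpec("II", 0.08, 4200.0, 4.5, 0.8),
            LayerSpec("III", 0.24, 2500.0, 6.0, 1.2),
            LayerSpec("IVa", 0.06, 4400.0, 4.5, 0.8),
            LayerSpec("IVb", 0.06, 3200.0, 5.0, 1.0),
            LayerSpec("IVc", 0.11, 6500.0, 4.5, 0.8),
            LayerSpec("V", 0.12, 900.0, 5.0, 1.0),
            LayerSpec("VI", 0.23, 3800.0, 5.0, 1.0),
        )
        return AreaProfile("hOc1-like", layers, columnarity=0.2)
    if kind == "hOc2-like":
        layers = (
            LayerSpec("I", 0.10, 500.0, 4.0, 0.8),
            LayerSpec("II", 0.09, 3000.0, 4.5, 0.8),
            LayerSpec(
                "III", 0.29, 1700.0, 6.5, 1.2, radius_gradient=(5.0, 9.0)
            ),
            LayerSpec("IV", 0.10, 3600.0, 4.5, 0.8),
            LayerSpec("V", 0.16, 1300.0, 5.0, 1.0),
            LayerSpec("VI", 0.26, 2500.0, 5.0, 1.0),
        )
        return AreaProfile("hOc2-like", layers, columnarity=0.5)
    raise ValueError(
        f"unknown preset {kind!r}; valid presets: 'hOc1-like', 'hOc2-like'"
    )


# ---------------------------------------------------------------------------
# geometry helpers

def _flat_geometry(cfg: RenderConfig):
    """Depth field (um, NaN outside cortex) and masks for the flat ribbon."""
    h, w = cfg.height_px, cfg.width_px
    t_px = cfg.cortical_thickness_um / cfg.resolution_um_per_px
    margin = max(4.0, 0.06 * h)
    if t_px + margin + 4 > h:
        raise ValueError(
            f"cortical thickness {cfg.cortical_thickness_um} um "
            f"({t_px:.0f} px) does not fit the image height {h} px"
        )
    rows = np.arange(h, dtype=float)[:, None]
    depth_px = rows - margin  # 0 at pia
    depth_um = np.broadcast_to(depth_px * cfg.resolution_um_per_px, (h, w)).copy()
    cortex = (depth_px >= 0) & (depth_px < t_px)
    cortex = np.broadcast_to(cortex, (h, w)).copy()
    wm = np.broadcast_to(depth_px >= t_px, (h, w)).copy()
    # lateral coordinate for area assignment and columns: column index in um
    lateral_um = np.broadcast_to(
        np.arange(w, dtype=float)[None, :] * cfg.resolution_um_per_px, (h, w)
    ).copy()
    return depth_um, cortex, wm, lateral_um, ("flat", margin, t_px)


def _arc_geometry(cfg: RenderConfig):
    """Annulus-sector ribbon: pia at outer radius, WM inside."""
    h, w = cfg.height_px, cfg.width_px
    res = cfg.resolution_um_per_px
    t_px = cfg.cortical_thickness_um / res
    # centre below the image so the ribbon curves across the frame
    r_outer = 0.95 * h + 0.45 * h  # generous outer radius in px
    cx = w / 2.0
    cy = 0.06 * h + r_outer  # centre row (below image bottom)
    if t_px + 8 > r_outer:
        raise ValueError("cortical thickness exceeds the arc geometry extent")
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    radius = np.hypot(rr - cy, cc - cx)
    depth_px = r_outer - radius  # 0 at pia, grows inward (downward)
    depth_um = depth_px * res
    cortex = (depth_px >= 0) & (depth_px < t_px)
    wm = depth_px >= t_px
    # lateral coordinate = arc length along the pia from the sector's left edge
    theta = np.arctan2(cc - cx, cy - rr)  # 0 at top, increasing to the right
    lateral_um = (theta - theta.min()) * r_outer * res
    return depth_um, cortex, wm, lateral_um, ("arc", cx, cy, r_outer, t_px)


def _contour_points(cfg: RenderConfig, geom, rel_depth: float, n: int = 512):
    """Polyline at a fixed relative cortical depth, ordered by lateral position."""
    res = cfg.resolution_um_per_px
    if geom[0] == "flat":
        _, margin, t_px = geom
        row = margin + rel_depth * t_px
        cols = np.linspace(0, cfg.width_px - 1, n)
        return np.column_stack([np.full(n, row), cols])
    _, cx, cy, r_outer, t_px = geom
    radius = r_outer - rel_depth * t_px
    # angular span covering the image width at the pial radius
    half = np.arcsin(min(0.999, (cfg.width_px / 2.0) / r_outer))
    theta = np.linspace(-half, half, n)
    rows = cy - radius * np.cos(theta)
    cols = cx + radius * np.sin(theta)
    keep = (rows >= 0) & (rows < cfg.height_px) & (cols >= 0) & (cols < cfg.width_px)
    return np.column_stack([rows[keep], cols[keep]])


def contour_arclength_um(contour: np.ndarray, resolution_um_per_px: float) -> np.ndarray:
    """Cumulative arc length (um) along a (row, col) polyline, starting at 0."""
    d = np.hypot(*np.diff(contour, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(d)]) * resolution_um_per_px


# ---------------------------------------------------------------------------
# rendering

def render_phantom(
    profiles: list[AreaProfile] | tuple[AreaProfile, ...],
    config: RenderConfig,
) -> CorticalPhantom:
    """Render a phantom of one or more laterally adjacent areas.

    Cell bodies are placed by an inhomogeneous Poisson point process with the
    per-layer densities, optionally thinned by a vertical stripe pattern
    (columnarity), and drawn as filled ellipses (aspect ratio 1-1.6) at each
    layer's stain intensity.  Gaussian pixel noise of sd ``config.noise_sd``
    is added and the result clipped to [0, 255].  Fully deterministic for a
    fixed seed.
    """
    profiles = tuple(profiles)
    if not profiles:
        raise ValueError("need at least one area profile")
    ids = [p.area_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("area_id values must be unique within a phantom")

    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    res = config.resolution_um_per_px

    if config.geometry == "flat":
        depth_um, cortex, wm, lateral_um, geom = _flat_geometry(config)
    else:
        depth_um, cortex, wm, lateral_um, geom = _arc_geometry(config)

    # ----- area assignment: equal lateral bands in arc-length
    lat_min = lateral_um[cortex].min() if cortex.any() else 0.0
    lat_max = lateral_um[cortex].max() if cortex.any() else 1.0
    n_areas = len(profiles)
    edges = np.linspace(lat_min, lat_max, n_areas + 1)
    area_labels = np.zeros((h, w), dtype=np.uint16)
    area_labels[wm] = WHITE_MATTER_LABEL
    area_of_pixel = np.full((h, w), -1, dtype=np.int32)
    for k in range(n_areas):
        lo, hi = edges[k], edges[k + 1]
        band = cortex & (lateral_um >= lo) & (
            lateral_um < hi if k < n_areas - 1 else lateral_um <= hi
        )
        area_labels[band] = _FIRST_AREA_LABEL + k
        area_of_pixel[band] = k

    # ----- layer assignment per area (relative depth bands)
    rel_depth = depth_um / config.cortical_thickness_um
    layer_labels = np.zeros((h, w), dtype=np.uint16)
    layer_names: dict[int, str] = {}
    next_layer_id = 1
    layer_regions = []  # (area_idx, layer_idx, layer_id, mask)
    for k, prof in enumerate(profiles):
        bounds = np.concatenate([[0.0], np.cumsum([l.thickness_fraction for l in prof.layers])])
        in_area = area_of_pixel == k
        for j, layer in enumerate(prof.layers):
            lo, hi = bounds[j], bounds[j + 1]
            m = in_area & (rel_depth >= lo) & (
                rel_depth < hi if j < len(prof.layers) - 1 else rel_depth <= hi + 1e-12
            )
            layer_labels[m] = next_layer_id
            layer_names[next_layer_id] = f"{prof.area_id}/{layer.name}"
            layer_regions.append((k, j, next_layer_id, m))
            next_layer_id += 1

    # ----- base image
    image = np.full((h, w), float(BACKGROUND_GREY))
    image[cortex] = CORTEX_GREY
    image[wm] = WM_GREY

    # ----- cell placement.  Each layer region uses its own substream and the
    # Poisson count is drawn by quantile inversion of a fixed uniform, with
    # per-cell attribute substreams: raising one layer's density then only
    # appends cells (the first N cells are identical draws), so the rendered
    # foreground can never shrink and other layers are untouched.
    cell_mask = np.zeros((h, w), dtype=bool)
    px_area_mm2 = (res / 1000.0) ** 2
    from scipy import stats as _stats

    for k, j, layer_id, region in layer_regions:
        prof = profiles[k]
        layer = prof.layers[j]
        n_px = int(region.sum())
        if n_px == 0 or layer.cell_density <= 0:
            continue
        lam = layer.cell_density * n_px * px_area_mm2
        u_count = np.random.default_rng((config.seed, k, j, 1)).uniform()
        n_cells = int(_stats.poisson.ppf(u_count, lam))
        if n_cells == 0:
            continue
        ridx, cidx = np.nonzero(region)
        bounds = np.concatenate(
            [[0.0], np.cumsum([l.thickness_fraction for l in prof.layers])]
        )
        lo_b, hi_b = bounds[j], bounds[j + 1]
        # columns are locally but not globally coherent: the stripe phase
        # drifts smoothly along the ribbon (random long-wavelength sinusoids
        # per area, independent of the cell draws)
        if prof.columnarity > 0:
            pg = np.random.default_rng((config.seed, k, 3))
            drift = [
                (pg.uniform(0.7, 1.6), pg.uniform(300.0, 1200.0), pg.uniform(0, 2 * np.pi))
                for _ in range(4)
            ]

            def stripe_phase(lat):
                return sum(a * np.sin(2 * np.pi * lat / L + th) for a, L, th in drift)
        for i in range(n_cells):
            cg = np.random.default_rng((config.seed, k, j, 2, i))
            p = int(cg.integers(0, n_px))
            cy_px = ridx[p] + cg.uniform(-0.5, 0.5)
            cx_px = cidx[p] + cg.uniform(-0.5, 0.5)
            # columnar thinning: stripes of period 50 um laterally
            if prof.columnarity > 0:
                lat = lateral_um[ridx[p], cidx[p]]
                c = prof.columnarity
                phase = 2 * np.pi * lat / 50.0 + stripe_phase(lat)
                accept_p = (1.0 + c * np.cos(phase)) / (1.0 + c)
                if cg.uniform() >= accept_p:
                    continue
            if layer.radius_gradient is not None:
                t = (rel_depth[ridx[p], cidx[p]] - lo_b) / max(hi_b - lo_b, 1e-12)
                r_mean = layer.radius_gradient[0] + t * (
                    layer.radius_gradient[1] - layer.radius_gradient[0]
                )
            else:
                r_mean = layer.cell_radius_mean
            radius_um = max(cg.normal(r_mean, layer.cell_radius_sd), 1.0)
            radius_px = max(radius_um / res, 0.6)
            aspect = cg.uniform(1.0, 1.6)
            orient = cg.uniform(0.0, np.pi)
            rr, cc = _draw_ellipse(
                cy_px, cx_px, radius_px, radius_px / aspect,
                shape=(h, w), rotation=orient,
            )
            if rr.size == 0:
                continue
            inside = region[rr, cc]
            rr, cc = rr[inside], cc[inside]
            image[rr, cc] = layer.stain_intensity
            cell_mask[rr, cc] = True

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=(h, w))
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    # ----- contours and true border
    layer1_frac = profiles[0].layers[0].thickness_fraction
    outer = _contour_points(config, geom, layer1_frac)
    inner = _contour_points(config, geom, 1.0)
    arc = contour_arclength_um(outer, res)
    # border positions: lateral band edges mapped to outer-contour arc length
    if geom[0] == "flat":
        lat_of_outer = outer[:, 1] * res
    else:
        # lateral coordinate of the outer-contour points
        rr = outer[:, 0].astype(int).clip(0, h - 1)
        cc = outer[:, 1].astype(int).clip(0, w - 1)
        lat_of_outer = lateral_um[rr, cc]
    true_border = []
    for e in edges[1:-1]:
        i = int(np.argmin(np.abs(lat_of_outer - e)))
        true_border.append(float(arc[i]))

    return CorticalPhantom(
        image=image,
        cell_mask=cell_mask,
        layer_labels=layer_labels,
        area_labels=area_labels,
        outer_contour=outer,
        inner_contour=inner,
        true_border_um=true_border,
        config=config,
        profiles=profiles,
        layer_names=layer_names,
    )


# ---------------------------------------------------------------------------
# serialization

def save_phantom(phantom: CorticalPhantom, out_dir: str | Path) -> None:
    """Write image/masks as TIFF, contours + metadata as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "image.tif", phantom.image)
    tifffile.imwrite(out / "cell_mask.tif", phantom.cell_mask.astype(np.uint8))
    tifffile.imwrite(out / "layer_labels.tif", phantom.layer_labels)
    tifffile.imwrite(out / "area_labels.tif", phantom.area_labels)
    cfg = phantom.config
    meta = {
        "outer_contour": phantom.outer_contour.tolist(),
        "inner_contour": phantom.inner_contour.tolist(),
        "true_border_um": phantom.true_border_um,
        "layer_names": {str(k): v for k, v in phantom.layer_names.items()},
        "config": {
            "resolution_um_per_px": cfg.resolution_um_per_px,
            "width_px": cfg.width_px,
            "height_px": cfg.height_px,
            "cortical_thickness_um": cfg.cortical_thickness_um,
            "geometry": cfg.geometry,
            "noise_sd": cfg.noise_sd,
            "seed": cfg.seed,
        },
    }
    (out / "phantom.json").write_text(json.dumps(meta))


def load_phantom(in_dir: str | Path) -> CorticalPhantom:
    """Load a phantom written by :func:`save_phantom` (profiles not restored)."""
    p = Path(in_dir)
    meta = json.loads((p / "phantom.json").read_text())
    cfg = RenderConfig(**meta["config"])
    return CorticalPhantom(
        image=tifffile.imread(p / "image.tif"),
        cell_mask=tifffile.imread(p / "cell_mask.tif").astype(bool),
        layer_labels=tifffile.imread(p / "layer_labels.tif"),
        area_labels=tifffile.imread(p / "area_labels.tif"),
        outer_contour=np.asarray(meta["outer_contour"], dtype=float),
        inner_contour=np.asarray(meta["inner_contour"], dtype=float),
        true_border_um=list(meta["true_border_um"]),
        config=cfg,
        layer_names={int(k): v for k, v in meta["layer_names"].items()},
    )
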
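"""Filter-activation similarity and cytoarchitectonic feature levels.

Workflow over an :class:`~cortexmap.cnn_arch.ActivationStack`:

1. normalize each post-ReLU map to [0, 1] with the smallest *strictly
   positive* value as lower bound (zeros stay zero);
2. resample every map to the reference (input-image) resolution and build
   256-bin joint histograms (bin edges i/256, top bin closed) to compute
   pairwise mutual information in bits;
3. flag a unit *characteristic* for its network layer when at least 3 of
   its 12 highest-MI partners belong to the same layer;
4. score each characteristic map against phantom ground truth — rank
   correlation with local cell density (first level, cell bodies), best
   layer-vs-rest ranking separation (second level, laminar pattern), and
   area-vs-rest separation (third level, cortical areas) — and assign the
   winning level when its score clears the threshold.

Step 4 is a quantitative proxy for what is otherwise an expert's visual
categorization; it makes the categories reproducible on phantoms but is
not a claim of equivalence to expert judgement on real histology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .cnn_arch import ActivationStack
from .synthio import CorticalPhantom

__all__ = [
    "NormalizedMap",
    "MIMatrix",
    "CharacteristicSet",
    "LevelAssignment",
    "normalize_activation",
    "joint_histogram",
    "mutual_information",
    "entropy_bits",
    "pairwise_mi",
    "characteristic_filters",
    "assign_levels",
    "save_compilation_png",
    "N_BINS",
]

N_BINS = 256


@dataclass
class NormalizedMap:
    values: np.ndarray  # 2D float in [0, 1]
    degenerate: bool
    lower_bound: float  # the smallest strictly positive raw value used
    branch: str = ""
    network_layer: int = -1
    unit: int = -1


@dataclass
class MIMatrix:
    values: np.ndarray  # symmetric, diagonal = per-map entropy
    unit_of_information: str = "bits"
    n_bins: int = N_BINS
    degenerate: np.ndarray | None = None  # flags for all-zero maps


@dataclass
class CharacteristicSet:
    characteristic: np.ndarray  # bool per unit
    neighbours: list[list[int]]  # top-k MI partner indices per unit
    same_layer_count: np.ndarray
    k: int = 12
    min_same_layer: int = 3
    tie_broken: bool = False


@dataclass
class LevelAssignment:
    indices: list[int]  # stack indices of the characteristic maps scored
    score_cell: list[float] = field(default_factory=list)
    score_layer: list[float] = field(default_factory=list)
    score_area: list[float] = field(default_factory=list)
    level: list[str] = field(default_factory=list)  # first|second|third|unassigned
    thresholds: tuple[float, float, float] = (0.5, 0.85, 0.85)


def normalize_activation(raw: np.ndarray) -> NormalizedMap:
    """Map to [0, 1] with the smallest strictly positive value as lower bound.

    Values at or below the bound go to 0; the maximum goes to 1.  All-zero
    or constant maps come back all-zero with a degeneracy flag.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("activation map contains non-finite values")
    pos = raw[raw > 0]
    if pos.size == 0:
        return NormalizedMap(np.zeros_like(raw), True, 0.0)
    a = float(pos.min())
    m = float(raw.max())
    if m <= a:
        if raw.min() < a:
            # two-valued {0, c} map: not constant, but the formula is
            # 0/0 at its single positive level; take the natural limit
            return NormalizedMap((raw > 0).astype(float), False, a)
        return NormalizedMap(np.zeros_like(raw), True, a)
    out = np.clip((raw - a) / (m - a), 0.0, 1.0)
    return NormalizedMap(out, False, a)


def _bin_indices(values: np.ndarray) -> np.ndarray:
    """Bin edges i/256 for i=0..255, top bin closed at 1."""
    idx = np.floor(np.asarray(values, dtype=float) * N_BINS).astype(np.int64)
    return np.clip(idx, 0, N_BINS - 1)


def joint_histogram(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """256x256 joint probability table of two [0,1] maps of equal size."""
    x, y = np.asarray(x), np.asarray(y)
    if x.size != y.size:
        raise ValueError("maps differ in pixel count; resample first")
    ix = _bin_indices(x).ravel()
    iy = _bin_indices(y).ravel()
    counts = np.bincount(ix * N_BINS + iy, minlength=N_BINS * N_BINS)
    return counts.reshape(N_BINS, N_BINS) / x.size


def _mi_from_joint(p: np.ndarray) -> float:
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI in bits from the 256-bin joint histogram (0 log 0 := 0)."""
    return _mi_from_joint(joint_histogram(x, y))


def entropy_bits(x: np.ndarray) -> float:
    """256-bin Shannon entropy of one [0,1] map, in bits."""
    p = np.bincount(_bin_indices(x).ravel(), minlength=N_BINS) / x.size
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def resample_to_reference(values: np.ndarray, ref_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsampling of a coarse map to the reference grid."""
    if values.shape == tuple(ref_shape):
        return values
    zoom = (ref_shape[0] / values.shape[0], ref_shape[1] / values.shape[1])
    return ndimage.zoom(values, zoom, order=0, mode="nearest", grid_mode=True)


def pairwise_mi(
    stack: ActivationStack,
    ref_shape: tuple[int, int] | None = None,
    progress: bool = False,
) -> MIMatrix:
    """Symmetric MI matrix over all maps of a stack.

    Maps are normalized, resampled (nearest) to the reference resolution
    (the largest map by default) and digitized once; each unordered pair is
    then a single 256^2 bincount.  Degenerate (all-zero) maps get MI 0 and
    entropy 0, flagged.  Diagonal entries are each map's own entropy.
    """
    n = len(stack)
    if n < 2:
        raise ValueError("need at least two maps")
    if ref_shape is None:
        ref_shape = max((m.shape for m in stack.maps), key=lambda s: s[0] * s[1])
    digitized = []
    degenerate = np.zeros(n, dtype=bool)
    for m in stack.maps:
        nm = normalize_activation(m)
        degenerate[len(digitized)] = nm.degenerate
        res = resample_to_reference(nm.values, ref_shape)
        digitized.append(_bin_indices(res).ravel().astype(np.int32))
    npx = digitized[0].size
    mi = np.zeros((n, n))
    marg = [np.bincount(d, minlength=N_BINS) / npx for d in digitized]
    ent = np.array([
        float(-np.sum(p[p > 0] * np.log2(p[p > 0]))) for p in marg
    ])
    for i in range(n):
        mi[i, i] = 0.0 if degenerate[i] else ent[i]
        if degenerate[i]:
            continue
        if progress and i % 25 == 0:
            print(f"pairwise MI: row {i}/{n}")
        base = digitized[i] * N_BINS
        for j in range(i + 1, n):
            if degenerate[j]:
                continue
            counts = np.bincount(base + digitized[j], minlength=N_BINS * N_BINS)
            p = counts.reshape(N_BINS, N_BINS) / npx
            mi[i, j] = mi[j, i] = _mi_from_joint(p)
    return MIMatrix(values=mi, degenerate=degenerate)


def characteristic_filters(
    mi: MIMatrix,
    layer_assignment,
    k: int = 12,
    min_same_layer: int = 3,
) -> CharacteristicSet:
    """Flag units whose top-k MI partners include >= min_same_layer same-layer units.

    ``layer_assignment`` maps each map index to its network layer.  Ties at
    rank k break toward the lower unit index (flagged).
    """
    m = mi.values
    n = m.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of maps")
    layers = np.asarray(layer_assignment)
    neighbours, same_counts = [], np.zeros(n, dtype=int)
    tie_broken = False
    for i in range(n):
        row = m[i].copy()
        row[i] = -np.inf
        # sort by (-MI, index): equal MI -> lower index first
        order = np.lexsort((np.arange(n), -row))
        top = order[:k]
        if k < n - 1 and row[order[k - 1]] == row[order[k]]:
            tie_broken = True
        neighbours.append(top.tolist())
        same_counts[i] = int(np.sum(layers[top] == layers[i]))
    flags = same_counts >= min_same_layer
    return CharacteristicSet(
        characteristic=flags, neighbours=neighbours,
        same_layer_count=same_counts, k=k, min_same_layer=min_same_layer,
        tie_broken=tie_broken,
    )


# ---------------------------------------------------------------------------
# feature-level assignment against phantom ground truth

def _auc(values: np.ndarray, positive: np.ndarray) -> float:
    """Two-class ranking separation (area under the ranking curve).

    Symmetric: a map that singles a region out by *low* values separates
    just as well, so max(AUC, 1-AUC) is returned.
    """
    pos = values[positive]
    neg = values[~positive]
    if pos.size == 0 or neg.size == 0:
        return 0.0
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    auc = (r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)
    return float(max(auc, 1.0 - auc))


def local_cell_density(phantom: CorticalPhantom, window_um: float = 20.0) -> np.ndarray:
    """Cell-mask fraction in a sliding square window (fine-scale density)."""
    w = max(1, int(round(window_um / phantom.config.resolution_um_per_px)))
    return ndimage.uniform_filter(phantom.cell_mask.astype(float), size=w)


def assign_levels(
    stack: ActivationStack,
    charset: CharacteristicSet,
    phantom: CorticalPhantom,
    thresholds: tuple[float, float, float] = (0.5, 0.85, 0.85),
    max_eval_px: int = 200_000,
    seed: int = 0,
) -> LevelAssignment:
    """Score characteristic maps against masks and assign feature levels.

    score_cell: Spearman rank correlation (absolute value) between map
    values and local cell density over cortex pixels — cell-body features.
    score_layer: best layer-vs-rest-of-cortex ranking separation — laminar
    features.  score_area: area-vs-rest-of-tissue separation — area-level
    features.  The level with the highest score wins if it clears its
    threshold (cell, layer, area); otherwise the map stays unassigned.
    Scores are evaluated on a seeded random subsample of pixels for speed.
    """
    cortex = phantom.cortex_mask()
    tissue = phantom.area_labels > 0
    ref_shape = phantom.image.shape
    density = local_cell_density(phantom)
    rng = np.random.default_rng(seed)

    cortex_idx = np.nonzero(cortex.ravel())[0]
    tissue_idx = np.nonzero(tissue.ravel())[0]
    if cortex_idx.size > max_eval_px:
        cortex_idx = rng.choice(cortex_idx, max_eval_px, replace=False)
    if tissue_idx.size > max_eval_px:
        tissue_idx = rng.choice(tissue_idx, max_eval_px, replace=False)

    layer_ids = np.unique(phantom.layer_labels[cortex])
    layer_ids = layer_ids[layer_ids > 0]
    area_ids = phantom.area_ids
    lab_flat = phantom.layer_labels.ravel()[cortex_idx]
    area_flat = phantom.area_labels.ravel()[tissue_idx]
    area_of_cortex = phantom.area_labels.ravel()[cortex_idx]
    dens_flat = density.ravel()[cortex_idx]

    result = LevelAssignment(indices=[], thresholds=thresholds)
    t_cell, t_layer, t_area = thresholds
    for i in np.nonzero(charset.characteristic)[0]:
        nm = normalize_activation(stack.maps[i])
        if nm.degenerate:
            continue
        full = resample_to_reference(nm.values, ref_shape)
        v_cortex = full.ravel()[cortex_idx]
        v_tissue = full.ravel()[tissue_idx]
        # fine-scale cell correspondence: rank correlation with local cell
        # density *within* each area (pixel-weighted mean), so a map that
        # merely tells the areas apart scores ~0 here
        corrs, weights = [], []
        for aid in area_ids:
            sel = area_of_cortex == aid
            if sel.sum() < 10 or np.ptp(v_cortex[sel]) == 0:
                continue  # constant over the area: no rank correlation
            r = stats.spearmanr(v_cortex[sel], dens_flat[sel]).statistic
            if np.isfinite(r):
                corrs.append(abs(float(r)))
                weights.append(int(sel.sum()))
        s_cell = float(np.average(corrs, weights=weights)) if corrs else 0.0
        s_layer = max(_auc(v_cortex, lab_flat == lid) for lid in layer_ids)
        s_area = max(_auc(v_tissue, area_flat == aid) for aid in area_ids)
        scores = {"first": s_cell, "second": s_layer, "third": s_area}
        ths = {"first": t_cell, "second": t_layer, "third": t_area}
        best = max(scores, key=lambda lv: scores[lv])
        level = best if scores[best] >= ths[best] else "unassigned"
        result.indices.append(int(i))
        result.score_cell.append(s_cell)
        result.score_layer.append(s_layer)
        result.score_area.append(s_area)
        result.level.append(level)
    return result


def save_compilation_png(
    stack: ActivationStack,
    charset: CharacteristicSet,
    unit_index: int,
    path,
    cmap_name: str = "cividis",
) -> None:
    """Top-12 gallery for one unit, lightness-ordered colour map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = [unit_index] + list(charset.neighbours[unit_index])
    cols = 4
    rows = -(-len(ids) // cols)
    fig, axes = plt.subplots(rows, cols, figsize=(3 * cols, 3 * rows))
    for ax, i in zip(np.ravel(axes), ids):
        nm = normalize_activation(stack.maps[i])
        ax.imshow(nm.values, cmap=cmap_name, vmin=0, vmax=1)
        ax.set_title(f"L{stack.network_layer[i]} u{stack.unit[i]}", fontsize=8)
        ax.axis("off")
    for ax in np.ravel(axes)[len(ids):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
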
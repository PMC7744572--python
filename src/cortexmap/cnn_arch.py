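"""Dual-branch contracting/expanding segmentation architecture.

The architecture follows the multi-scale U-Net variant used for
cytoarchitectonic area segmentation: a high-resolution contracting branch
(fine cytoarchitectonic detail, 2025 px patches at 2 um/px = 4.05 mm field
of view), a low-resolution contracting branch (tissue context, 1123 px at
16 um/px = 17.97 mm) and a single expanding branch that combines both.
Contracting blocks are two convolution layers plus pooling; expanding
blocks are an up-convolution plus two convolutions; every convolution is
followed by batch normalization and a ReLU.  The default configuration has
10 blocks, 24 network layers and exactly 864 units per branch (2592 per
network instance); the per-layer split of the 864 is a documented default,
validated hard at construction.

Two levels of realization exist side by side:

* ``build_architecture`` enumerates the full-size architecture as a
  description (unit bookkeeping, block/branch membership) without
  allocating weights;
* ``make_model`` instantiates a desk-scale version (unit counts and patch
  sizes divided by ``reduced``, default 8) as a trainable numpy network,
  used for the phantom experiments and activation analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .synthio import CorticalPhantom, BACKGROUND_LABEL, WHITE_MATTER_LABEL

__all__ = [
    "ArchitectureConfig",
    "LayerInfo",
    "PatchSample",
    "ActivationStack",
    "build_architecture",
    "field_of_view",
    "sample_patches",
    "make_model",
    "train_segmenter",
    "predict_image",
    "extract_activations",
    "total_activation_maps",
    "DualBranchUNet",
    "CLASS_NAMES",
]

CLASS_NAMES = ("background", "white_matter", "area_of_interest", "other_cortex")
N_CLASSES = 4


@dataclass(frozen=True)
class ArchitectureConfig:
    """Unit allocation and patch geometry of one network instance.

    Branch allocations are per *network layer* (convolution or
    up-convolution); each must sum to ``units_per_branch``.  The default
    split -- hr contracting 4 blocks (8 layers), lr contracting 2 blocks
    (4 layers), expanding 4 blocks (12 layers) = 10 blocks / 24 layers --
    is the repository's documented default; the totals are the hard
    constraint.
    """

    hr_blocks: tuple[tuple[int, ...], ...] = ((48, 48), (96, 96), (144, 144), (144, 144))
    lr_blocks: tuple[tuple[int, ...], ...] = ((144, 144), (288, 288))
    exp_blocks: tuple[tuple[int, ...], ...] = (
        (144, 144, 144), (72, 72, 72), (48, 48, 48), (24, 24, 24))
    units_per_branch: int = 864
    hr_patch_px: int = 2025
    hr_resolution_um: float = 2.0
    lr_patch_px: int = 1123
    lr_resolution_um: float = 16.0
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        for name, blocks in (("hr", self.hr_blocks), ("lr", self.lr_blocks),
                             ("expanding", self.exp_blocks)):
            total = sum(sum(b) for b in blocks)
            if total != self.units_per_branch:
                raise ValueError(
                    f"{name} branch units sum to {total}, "
                    f"expected {self.units_per_branch}"
                )
        for b in self.exp_blocks:
            if len(b) != 3:
                raise ValueError("expanding blocks are up-conv + two convs (3 layers)")
        for b in self.hr_blocks + self.lr_blocks:
            if len(b) != 2:
                raise ValueError("contracting blocks are two convolutions")

    @property
    def n_blocks(self) -> int:
        return len(self.hr_blocks) + len(self.lr_blocks) + len(self.exp_blocks)

    @property
    def n_network_layers(self) -> int:
        return sum(len(b) for b in
                   self.hr_blocks + self.lr_blocks + self.exp_blocks)

    @property
    def total_units(self) -> int:
        return 3 * self.units_per_branch

    def scaled(self, factor: float) -> "ArchitectureConfig":
        """Desk-scale copy: unit counts multiplied by ``factor``."""

        def sc(blocks):
            return tuple(tuple(max(1, int(round(u * factor))) for u in b) for b in blocks)

        hr, lr, ex = sc(self.hr_blocks), sc(self.lr_blocks), sc(self.exp_blocks)
        per_branch = sum(sum(b) for b in hr)
        if (sum(sum(b) for b in lr) != per_branch
                or sum(sum(b) for b in ex) != per_branch):
            raise ValueError("scaling factor breaks the equal-branch constraint")
        return replace(
            self, hr_blocks=hr, lr_blocks=lr, exp_blocks=ex,
            units_per_branch=per_branch,
        )


@dataclass(frozen=True)
class LayerInfo:
    branch: str  # "hr" | "lr" | "expanding"
    network_layer: int  # 1..24 (hr first, then lr, then expanding)
    block: int  # 1..10
    units: int
    kind: str  # "conv" | "upconv"


def build_architecture(config: ArchitectureConfig | None = None) -> list[LayerInfo]:
    """Enumerate every network layer of one instance with unit bookkeeping."""
    cfg = config or ArchitectureConfig()
    layers: list[LayerInfo] = []
    nl = 0
    blk = 0
    for branch, blocks in (("hr", cfg.hr_blocks), ("lr", cfg.lr_blocks)):
        for b in blocks:
            blk += 1
            for units in b:
                nl += 1
                layers.append(LayerInfo(branch, nl, blk, units, "conv"))
    for b in cfg.exp_blocks:
        blk += 1
        for j, units in enumerate(b):
            nl += 1
            layers.append(LayerInfo("expanding", nl, blk, units,
                                    "upconv" if j == 0 else "conv"))
    return layers


def field_of_view(patch_px: int, resolution_um_per_px: float) -> float:
    """Patch extent in mm, rounded to 2 decimals (e.g. 2025 px @ 2 um -> 4.05)."""
    if patch_px <= 0 or resolution_um_per_px <= 0:
        raise ValueError("patch size and resolution must be positive")
    return round(patch_px * resolution_um_per_px / 1000.0, 2)


def total_activation_maps(configs, branches: str = "all") -> int:
    """Number of per-unit activation maps over a set of network instances."""
    total = 0
    for cfg in configs:
        for info in build_architecture(cfg):
            if branches == "all" or info.branch in branches:
                total += info.units
    return total


# ---------------------------------------------------------------------------
# patch sampling

@dataclass
class PatchSample:
    hr: np.ndarray  # (hr_px, hr_px) float32 in [0, 1]
    lr: np.ndarray  # (lr_px, lr_px) float32 in [0, 1]
    label: int  # class of the centre pixel
    label_map: np.ndarray  # (hr_px, hr_px) int8 per-pixel classes
    center: tuple[int, int]


def _class_map(phantom: CorticalPhantom, area_of_interest: int) -> np.ndarray:
    al = phantom.area_labels
    cm = np.full(al.shape, 3, dtype=np.int8)  # other cortex
    cm[al == BACKGROUND_LABEL] = 0
    cm[al == WHITE_MATTER_LABEL] = 1
    cm[al == area_of_interest] = 2
    return cm


def _lr_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample, padding to a multiple of ``factor`` with edge values."""
    h, w = image.shape
    ph = (-h) % factor
    pw = (-w) % factor
    img = np.pad(image.astype(np.float32), ((0, ph), (0, pw)), mode="edge")
    hh, ww = img.shape
    return img.reshape(hh // factor, factor, ww // factor, factor).mean(axis=(1, 3))


def sample_patches(
    phantom: CorticalPhantom,
    n_per_class: int,
    seed: int,
    hr_patch_px: int = 64,
    lr_factor: int = 8,
    area_of_interest: int | None = None,
) -> list[PatchSample]:
    """Draw exactly ``n_per_class`` co-centred hr/lr patch pairs per class.

    Classes: background, white matter, area of interest, other cortex.  The
    class label is taken at the patch centre; a per-pixel class map over the
    hr patch is attached for segmentation training.  Deterministic in seed.
    """
    if area_of_interest is None:
        area_of_interest = phantom.area_ids[0]
    cm = _class_map(phantom, area_of_interest)
    img = phantom.image.astype(np.float32) / 255.0
    lr_img = _lr_image(img, lr_factor)
    half = hr_patch_px // 2
    lr_half = hr_patch_px // 2  # lr patch: same pixel count, 8x extent
    rng = np.random.default_rng(seed)

    def crop(arr, r, c, size):
        """Edge-padded crop of ``size`` x ``size`` centred at (r, c)."""
        h, w = arr.shape
        r0, c0 = r - size // 2, c - size // 2
        rs, re = max(0, r0), min(h, r0 + size)
        cs, ce = max(0, c0), min(w, c0 + size)
        out = np.empty((size, size), dtype=arr.dtype)
        inner = arr[rs:re, cs:ce]
        pt, pb = rs - r0, r0 + size - re
        pl, pr = cs - c0, c0 + size - ce
        out[...] = np.pad(inner, ((pt, pb), (pl, pr)), mode="edge")
        return out

    samples: list[PatchSample] = []
    for cls in range(N_CLASSES):
        rr, cc = np.nonzero(cm == cls)
        if rr.size == 0:
            raise ValueError(f"class '{CLASS_NAMES[cls]}' absent from the phantom")
        pick = rng.integers(0, rr.size, size=n_per_class)
        for p in pick:
            r, c = int(rr[p]), int(cc[p])
            samples.append(PatchSample(
                hr=crop(img, r, c, hr_patch_px),
                lr=crop(lr_img, r // lr_factor, c // lr_factor, hr_patch_px),
                label=cls,
                label_map=crop(cm, r, c, hr_patch_px),
                center=(r, c),
            ))
    return samples


# ---------------------------------------------------------------------------
# desk-scale trainable network

class DualBranchUNet:
    """Trainable desk-scale realization of the dual-branch architecture.

    Input: co-centred hr and lr greyscale patches (lr covering 8x the
    extent at 8x coarser sampling).  Output: per-pixel logits over the four
    tissue classes on the hr patch grid.  The hr branch pools four times;
    the lr branch twice; lr bottom features are 2x-upsampled, centre-cropped
    to the hr bottom grid and concatenated (the junction), then four
    expanding blocks with skip connections restore full resolution.
    """

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng((seed, 0xA))
        c = [b for blk in config.hr_blocks for b in blk]  # 8 conv widths
        d = [b for blk in config.lr_blocks for b in blk]  # 4 conv widths
        e = config.exp_blocks  # 4 blocks of 3

        def cbr(cin, cout):
            return nn.ConvBNReLU(cin, cout, rng=rng)

        self.hr_layers = [
            [cbr(1, c[0]), cbr(c[0], c[1])],
            [cbr(c[1], c[2]), cbr(c[2], c[3])],
            [cbr(c[3], c[4]), cbr(c[4], c[5])],
            [cbr(c[5], c[6]), cbr(c[6], c[7])],
        ]
        self.lr_layers = [
            [cbr(1, d[0]), cbr(d[0], d[1])],
            [cbr(d[1], d[2]), cbr(d[2], d[3])],
        ]
        skip_ch = [c[1], c[3], c[5], c[7]]
        cin = c[7] + d[3]
        self.exp_layers = []
        for blk_i, (u0, u1, u2) in enumerate(e):
            up = nn.UpConvBNReLU(cin, u0, rng=rng)
            cv1 = cbr(u0 + skip_ch[3 - blk_i], u1)
            cv2 = cbr(u1, u2)
            self.exp_layers.append([up, cv1, cv2])
            cin = u2
        self.head = nn.Conv2d(cin, config.n_classes, k=1, rng=rng)
        self.pools = [nn.MaxPool2d() for _ in range(6)]

    # -- bookkeeping -------------------------------------------------------
    def all_layers(self):
        out = []
        nl = 0
        for blk in self.hr_layers:
            for lay in blk:
                nl += 1
                out.append(("hr", nl, lay))
        for blk in self.lr_layers:
            for lay in blk:
                nl += 1
                out.append(("lr", nl, lay))
        for blk in self.exp_layers:
            for lay in blk:
                nl += 1
                out.append(("expanding", nl, lay))
        return out

    def params(self):
        ps = []
        for _, _, lay in self.all_layers():
            ps.extend(lay.params())
        ps.extend(self.head.params())
        return ps

    # -- forward/backward --------------------------------------------------
    def forward(self, hr, lr, train=True, record=None):
        """hr: (B,1,H,W) with H % 32 == 0; lr: (B,1,H,W) covering 8x extent."""

        def rec(branch, x):
            if record is not None:
                record.append((branch, x.copy()))

        skips = []
        x = hr
        for i, blk in enumerate(self.hr_layers):
            for lay in blk:
                x = lay.forward(x, train)
                rec("hr", x)
            skips.append(x)
            x = self.pools[i].forward(x, train)
        y = lr
        for i, blk in enumerate(self.lr_layers):
            for lay in blk:
                y = lay.forward(y, train)
                rec("lr", y)
            y = self.pools[4 + i].forward(y, train)
        # junction: upsample lr bottom 2x (nearest), centre-crop to hr bottom
        y_up = y.repeat(2, axis=2).repeat(2, axis=3)
        bh, bw = x.shape[2], x.shape[3]
        self._junction = (y.shape, y_up.shape, bh, bw)
        r0 = (y_up.shape[2] - bh) // 2
        c0 = (y_up.shape[3] - bw) // 2
        self._crop = (r0, c0)
        x = np.concatenate([x, y_up[:, :, r0:r0 + bh, c0:c0 + bw]], axis=1)
        self._split = self.hr_layers[-1][-1].cout
        for blk_i, (up, cv1, cv2) in enumerate(self.exp_layers):
            x = up.forward(x, train)
            rec("expanding", x)
            skip = skips[3 - blk_i]
            x = np.concatenate([x, skip], axis=1)
            x = cv1.forward(x, train)
            rec("expanding", x)
            x = cv2.forward(x, train)
            rec("expanding", x)
        return self.head.forward(x, train)

    def backward(self, grad):
        g = self.head.backward(grad)
        skip_grads = [None] * 4
        for blk_i in range(3, -1, -1):
            up, cv1, cv2 = self.exp_layers[blk_i]
            g = cv1.backward(cv2.backward(g))
            u = up.up.cout if hasattr(up, "up") else up.cout
            g_skip = g[:, u:, :, :]
            skip_grads[3 - blk_i] = g_skip
            g = up.backward(np.ascontiguousarray(g[:, :u, :, :]))
        # split junction grad
        ch_hr = self._split
        g_hr_bottom = np.ascontiguousarray(g[:, :ch_hr])
        g_lr_up = g[:, ch_hr:]
        y_shape, y_up_shape, bh, bw = self._junction
        r0, c0 = self._crop
        g_up_full = np.zeros(y_up_shape, dtype=np.float32)
        g_up_full[:, :, r0:r0 + bh, c0:c0 + bw] = g_lr_up
        b, cch, h2, w2 = g_up_full.shape
        g_lr = g_up_full.reshape(b, cch, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        # lr branch backward
        gy = g_lr
        for i in range(1, -1, -1):
            gy = self.pools[4 + i].backward(gy)
            for lay in reversed(self.lr_layers[i]):
                gy = lay.backward(gy)
        # hr branch backward
        gx = g_hr_bottom
        for i in range(3, -1, -1):
            gx = self.pools[i].backward(gx)
            gx = gx + skip_grads[i]
            for lay in reversed(self.hr_layers[i]):
                gx = lay.backward(gx)
        return gx

    # -- convenience -------------------------------------------------------
    def predict_logits(self, hr, lr):
        return self.forward(hr, lr, train=False)


def make_model(
    config: ArchitectureConfig | None = None,
    reduced: float = 1 / 8,
    seed: int = 0,
) -> DualBranchUNet:
    cfg = (config or ArchitectureConfig()).scaled(reduced)
    return DualBranchUNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# training / inference

def _batch_from_samples(samples, idx):
    hr = np.stack([samples[i].hr for i in idx])[:, None]
    lr = np.stack([samples[i].lr for i in idx])[:, None]
    lab = np.stack([samples[i].label_map for i in idx]).astype(np.int64)
    return hr, lr, lab


def train_segmenter(
    phantoms,
    config: ArchitectureConfig | None = None,
    reduced: float = 1 / 8,
    iterations: int = 300,
    batch_size: int = 8,
    lr_rate: float = 2e-3,
    n_patches_per_class: int = 64,
    hr_patch_px: int = 64,
    seed: int = 0,
    area_of_interest: int | None = None,
):
    """Train a desk-scale instance on phantom patches.

    Patches are pre-sampled balanced over the four classes from every
    training phantom; each iteration draws a random batch and takes one
    Adam step on the per-pixel cross entropy.  Fully seeded.  Returns
    (model, log) where log carries the loss trace.
    """
    model = make_model(config, reduced=reduced, seed=seed)
    samples = []
    for k, ph in enumerate(phantoms):
        samples.extend(sample_patches(
            ph, n_patches_per_class, seed=(seed * 1000 + 17 * k) % (2**31),
            hr_patch_px=hr_patch_px, area_of_interest=area_of_interest,
        ))
    rng = np.random.default_rng((seed, 0xB))
    opt = nn.Adam(model.params(), lr=lr_rate)
    losses = []
    for it in range(iterations):
        idx = rng.integers(0, len(samples), size=batch_size)
        hr, lrp, lab = _batch_from_samples(samples, idx)
        logits = model.forward(hr, lrp, train=True)
        loss, grad = nn.softmax_cross_entropy(logits, lab)
        if not math.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it}: {losses[-10:]}")
        opt.zero_grad()
        model.backward(grad)
        opt.step()
        losses.append(loss)
    return model, {"loss": losses, "n_samples": len(samples)}


def _pad_to_multiple(img: np.ndarray, m: int):
    h, w = img.shape
    ph, pw = (-h) % m, (-w) % m
    return np.pad(img, ((0, ph), (0, pw)), mode="edge"), (h, w)


def predict_image(model: DualBranchUNet, image: np.ndarray, lr_factor: int = 8):
    """Per-pixel class probabilities for a whole image (fully convolutional)."""
    img = np.asarray(image, dtype=np.float32) / 255.0
    padded, (h, w) = _pad_to_multiple(img, 32)
    hr = padded[None, None]
    lr = _lr_image(padded, lr_factor)[None, None]
    logits = model.predict_logits(hr, lr)[0]
    z = logits - logits.max(axis=0, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=0, keepdims=True)
    return probs[:, :h, :w]


def dice_score(pred_labels: np.ndarray, true_mask: np.ndarray,
               cls: int, within: np.ndarray | None = None) -> float:
    p = pred_labels == cls
    t = true_mask
    if within is not None:
        p, t = p & within, t & within
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


# ---------------------------------------------------------------------------
# activation extraction

@dataclass
class ActivationStack:
    """Per-unit post-ReLU activation maps with provenance."""

    maps: list[np.ndarray] = field(default_factory=list)  # 2D float32
    branch: list[str] = field(default_factory=list)
    network_layer: list[int] = field(default_factory=list)
    unit: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.maps)

    def layer_of(self, i: int) -> int:
        return self.network_layer[i]

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for i, m in enumerate(self.maps):
                d = f.create_dataset(f"map_{i:05d}", data=m, compression="gzip")
                d.attrs["branch"] = self.branch[i]
                d.attrs["network_layer"] = self.network_layer[i]
                d.attrs["unit"] = self.unit[i]

    @classmethod
    def load_h5(cls, path) -> "ActivationStack":
        import h5py

        st = cls()
        with h5py.File(path, "r") as f:
            for k in sorted(f.keys()):
                d = f[k]
                st.maps.append(d[()])
                st.branch.append(str(d.attrs["branch"]))
                st.network_layer.append(int(d.attrs["network_layer"]))
                st.unit.append(int(d.attrs["unit"]))
        return st


def extract_activations(
    model: DualBranchUNet,
    image: np.ndarray,
    branches=("hr", "expanding"),
    lr_factor: int = 8,
) -> ActivationStack:
    """Run the model on a whole image and collect per-unit ReLU maps.

    One 2D map per unit of the requested branches, each at the native
    resolution of its network layer, with (branch, network layer, unit)
    provenance.  Deeper layers yield coarser maps.
    """
    img = np.asarray(image, dtype=np.float32) / 255.0
    if img.shape[0] < 32 or img.shape[1] < 32:
        raise ValueError("image smaller than the minimum valid input (32 px)")
    padded, _ = _pad_to_multiple(img, 32)
    hr = padded[None, None]
    lr = _lr_image(padded, lr_factor)[None, None]
    record: list[tuple[str, np.ndarray]] = []
    model.forward(hr, lr, train=False, record=record)
    # assign network-layer indices in the fixed order hr(1..), lr(..), exp(..)
    layer_counters: dict[str, int] = {"hr": 0, "lr": 0, "expanding": 0}
    offsets = {
        "hr": 0,
        "lr": sum(len(b) for b in model.config.hr_blocks),
        "expanding": sum(len(b) for b in model.config.hr_blocks)
        + sum(len(b) for b in model.config.lr_blocks),
    }
    stack = ActivationStack()
    for branch, act in record:
        layer_counters[branch] += 1
        nl = offsets[branch] + layer_counters[branch]
        if branch not in branches:
            continue
        for u in range(act.shape[1]):
            stack.maps.append(np.ascontiguousarray(act[0, u]))
            stack.branch.append(branch)
            stack.network_layer.append(nl)
            stack.unit.append(u)
    return stack
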
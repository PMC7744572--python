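"""End-to-end orchestration on phantoms.

Chains the stages: phantom synthesis -> GLI image -> Laplacian traverses ->
mean-profile feature vectors -> sliding-window border detection, and
optionally the network path: desk-scale training -> activation extraction
-> pairwise MI -> characteristic filters -> feature-level assignment ->
comparison of the GLI border with the network's segmentation border.

A single global seed fans out to per-stage seeds by fixed offsets so each
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import border_detect, cnn_arch, gli, profile_features, synthio, traverses
from . import activation_analysis as aa

__all__ = ["RunConfig", "run_pipeline", "validate_config", "gli_border_positions"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Flat, fully serializable stage configuration."""

    presets: tuple[str, str] = ("hOc1-like", "hOc2-like")
    geometry: str = "flat"
    resolution_um_per_px: float = 4.0
    width_px: int = 672
    height_px: int = 448
    cortical_thickness_um: float = 1400.0
    noise_sd: float = 4.0
    field_size_um: float = 20.0
    threshold: float | None = None  # None -> Otsu
    n_traverses: int = 100
    n_profile_points: int = 100
    window_min: int = 15
    window_max: int = 24
    confirm_fraction: float = 0.8
    alpha: float = 0.05
    laplace_tol: float = 1e-4
    train: bool = False
    train_iterations: int = 250
    reduced: float = 1 / 8
    hr_patch_px: int = 64
    seed: int = 0

    def window_sizes(self) -> tuple[int, ...]:
        return tuple(range(self.window_min, self.window_max + 1))

    def to_flat(self) -> dict:
        d = dataclasses.asdict(self)
        d["presets"] = ",".join(self.presets)
        return d

    @classmethod
    def from_flat(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("presets"), str):
            d["presets"] = tuple(d["presets"].split(","))
        flds = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in flds})

    def save(self, path) -> None:
        lines = [f"{k}={v if v is not None else ''}" for k, v in self.to_flat().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            d[k.strip()] = _coerce(k.strip(), v.strip())
        return cls.from_flat(d)


def _coerce(key, v):
    if v == "":
        return None
    if key in ("presets", "geometry"):
        return v
    if v in ("True", "False"):
        return v == "True"
    try:
        iv = int(v)
        return iv
    except ValueError:
        pass
    try:
        return float(v)
    except ValueError:
        return v


def validate_config(config: RunConfig) -> list[str]:
    """Empty list iff all stage invariants are satisfiable."""
    v: list[str] = []
    if config.resolution_um_per_px <= 0:
        v.append("resolution_um_per_px: must be positive")
    if config.field_size_um <= 0:
        v.append("field_size_um: must be positive")
    elif config.resolution_um_per_px > 0:
        f = config.field_size_um / config.resolution_um_per_px
        if abs(f - round(f)) > 1e-9 or round(f) < 1:
            v.append("field_size_um: not an integer number of pixels at this resolution")
    if config.geometry not in ("flat", "arc"):
        v.append("geometry: must be 'flat' or 'arc'")
    for kind in config.presets:
        try:
            synthio.make_preset_profile(kind)
        except ValueError as e:
            v.append(f"presets: {e}")
    if config.window_min < 6:
        v.append("window_min: 2b - p - 1 >= 1 requires b >= 6 for 10 features")
    if config.window_max < config.window_min:
        v.append("window_max: smaller than window_min")
    if config.n_traverses < 2 * config.window_max:
        v.append("n_traverses: sequence shorter than twice the largest window")
    if not 0 < config.confirm_fraction <= 1:
        v.append("confirm_fraction: must lie in (0, 1]")
    if not 0 < config.alpha < 1:
        v.append("alpha: must lie in (0, 1)")
    if config.cortical_thickness_um / config.resolution_um_per_px + 30 > config.height_px:
        v.append("cortical_thickness_um: does not fit the image height")
    try:
        cnn_arch.ArchitectureConfig().scaled(config.reduced)
    except ValueError as e:
        v.append(f"reduced: {e}")
    if config.hr_patch_px % 32 != 0:
        v.append("hr_patch_px: must be a multiple of 32")
    return v


def gli_border_positions(phantom, config: RunConfig):
    """GLI-profile border detection on one phantom.

    Returns (result, trav_list, features, true_index, arclengths_um).
    """
    mask = gli.binarize_cells(phantom.image, config.threshold)
    g = gli.compute_gli(
        mask, config.field_size_um, config.resolution_um_per_px,
        threshold=gli.binarize_cells.last_threshold,
    )
    fld = traverses.solve_laplace(
        phantom.cortex_mask() & (phantom.layer_labels > 0),
        phantom.outer_contour, phantom.inner_contour, tol=config.laplace_tol,
    )
    travs = traverses.trace_traverses(fld, config.n_traverses)
    feats = []
    for t in travs:
        prof = traverses.sample_profile(g, t, config.n_profile_points)
        feats.append(profile_features.feature_vector(prof))
    result = border_detect.find_borders(
        feats, config.window_sizes(), config.confirm_fraction, config.alpha,
    )
    arcs_um = np.array([t.seed_arclength_px for t in travs]) * config.resolution_um_per_px
    true_idx = [int(np.argmin(np.abs(arcs_um - tb))) for tb in phantom.true_border_um]
    return result, travs, feats, true_idx, arcs_um


def _cnn_border_index(probs, travs, aoi_class=2):
    """Traverse index where the predicted area membership crosses 1/2."""
    frac = []
    for t in travs:
        pts = t.points[:: max(1, len(t.points) // 50)]
        rr = np.clip(pts[:, 0].astype(int), 0, probs.shape[1] - 1)
        cc = np.clip(pts[:, 1].astype(int), 0, probs.shape[2] - 1)
        lab = probs[:, rr, cc].argmax(axis=0)
        frac.append(float(np.mean(lab == aoi_class)))
    frac = np.asarray(frac)
    inside = frac > 0.5
    crossings = np.nonzero(np.diff(inside.astype(int)) != 0)[0]
    return [int(c) + 1 for c in crossings]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; write artifacts and a JSON + text report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "run.cfg")
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "config": config.to_flat(), "stages": {}}
    stage = "synth"
    try:
        profiles = [synthio.make_preset_profile(k) for k in config.presets]
        rc = synthio.RenderConfig(
            resolution_um_per_px=config.resolution_um_per_px,
            width_px=config.width_px, height_px=config.height_px,
            cortical_thickness_um=config.cortical_thickness_um,
            geometry=config.geometry, noise_sd=config.noise_sd,
            seed=config.seed + 1,
        )
        phantom = synthio.render_phantom(profiles, rc)
        synthio.save_phantom(phantom, out / "phantom")
        report["stages"]["synth"] = {
            "true_border_um": phantom.true_border_um,
            "n_cells_px": int(phantom.cell_mask.sum()),
        }

        stage = "borders"
        result, travs, feats, true_idx, arcs_um = gli_border_positions(phantom, config)
        agree, miss_a, miss_b = border_detect.border_agreement(
            result.confirmed, true_idx, arcs_um,
        )
        report["stages"]["borders"] = {
            "threshold_used": gli.binarize_cells.last_threshold,
            "confirmed": result.confirmed,
            "confirmation_fraction": result.confirmation_fraction,
            "true_border_index": true_idx,
            "agreement_um": [d for _, _, d in agree],
            "missed_true": miss_b,
            "window_sizes": list(result.window_sizes),
        }
        with open(out / "borders.json", "w") as f:
            json.dump(report["stages"]["borders"], f, indent=1)

        if config.train:
            stage = "train"
            model, log = cnn_arch.train_segmenter(
                [phantom], reduced=config.reduced,
                iterations=config.train_iterations,
                hr_patch_px=config.hr_patch_px, seed=config.seed + 2,
            )
            probs = cnn_arch.predict_image(model, phantom.image)
            pred = probs.argmax(axis=0)
            dice = cnn_arch.dice_score(
                pred, phantom.area_labels == phantom.area_ids[0], 2,
                within=phantom.cortex_mask(),
            )
            cnn_idx = _cnn_border_index(probs, travs)
            agree2, _, miss2 = border_detect.border_agreement(
                cnn_idx, true_idx, arcs_um,
            )
            stage = "activations"
            stack = cnn_arch.extract_activations(model, phantom.image)
            stage = "mi"
            small = tuple(s // 2 for s in phantom.image.shape)
            mi = aa.pairwise_mi(stack, ref_shape=small)
            charset = aa.characteristic_filters(mi, stack.network_layer)
            stage = "levels"
            levels = aa.assign_levels(stack, charset, phantom, seed=config.seed + 3)
            per_layer: dict[int, int] = {}
            for i in np.nonzero(charset.characteristic)[0]:
                per_layer[stack.network_layer[i]] = per_layer.get(
                    stack.network_layer[i], 0) + 1
            report["stages"]["cnn"] = {
                "final_loss": log["loss"][-1],
                "dice_area": dice,
                "cnn_border_index": cnn_idx,
                "cnn_vs_true_um": [d for _, _, d in agree2],
                "n_characteristic": int(charset.characteristic.sum()),
                "characteristic_per_layer": {str(k): v for k, v in sorted(per_layer.items())},
                "levels": {lv: levels.level.count(lv)
                           for lv in ("first", "second", "third", "unassigned")},
            }
    except Exception as e:
        report["failed_stage"] = stage
        report["error"] = str(e)
        with open(out / "report.json", "w") as f:
            json.dump(report, f, indent=1, default=str)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {e}") from e

    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=1, default=str)
    lines = [f"cortexmap run report (schema v{REPORT_SCHEMA_VERSION})"]
    for st, vals in report["stages"].items():
        lines.append(f"[{st}]")
        for k, v in vals.items():
            lines.append(f"  {k} = {v}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report
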
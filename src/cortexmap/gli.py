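"""Grey level index (GLI) images.

The GLI measures the areal (as proxy for volume) fraction of cell bodies in
small square measuring fields — by default 20 x 20 um — of a binarized
cell-body-stained image.  Cells stain dark, so the foreground of the
binarization is every pixel *strictly darker* than the threshold.  Each GLI
value is the foreground pixel count of its field divided by the field's
pixel count; trailing partial fields are discarded so all fields have equal
area, as the volume-fraction definition requires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

__all__ = ["GLIImage", "binarize_cells", "compute_gli", "save_gli", "load_gli"]

DEFAULT_FIELD_UM = 20.0


@dataclass
class GLIImage:
    """Grid of cell-body area fractions, one value per measuring field."""

    values: np.ndarray  # 2D float in [0, 1]
    field_size_um: float
    resolution_um_per_px: float  # of the *source* image
    threshold: float | None = None  # greyscale threshold used, if known

    @property
    def field_px(self) -> int:
        return int(round(self.field_size_um / self.resolution_um_per_px))

    def field_center_px(self, i: float, j: float) -> tuple[float, float]:
        """Source-image pixel coordinates (row, col) of field-grid point (i, j).

        Field (0, 0) is the top-left field; its centre sits at pixel
        (f/2 - 0.5, f/2 - 0.5) in the pixel-centre convention.
        """
        f = self.field_px
        return (i * f + f / 2.0 - 0.5, j * f + f / 2.0 - 0.5)


def binarize_cells(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binarize a greyscale image; foreground = pixels strictly darker.

    When ``threshold`` is None, Otsu's criterion picks it (the choice is
    recorded on the returned array via ``binarize_cells.last_threshold``).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        threshold = float(threshold_otsu(image))
        if np.issubdtype(image.dtype, np.integer):
            # Otsu returns the upper edge of the dark class on integer
            # images; half a grey level keeps the strictly-darker rule
            # inclusive of that class
            threshold += 0.5
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    binarize_cells.last_threshold = float(threshold)
    return image < threshold


binarize_cells.last_threshold = None  # type: ignore[attr-defined]


def compute_gli(
    mask: np.ndarray,
    field_size_um: float = DEFAULT_FIELD_UM,
    resolution_um_per_px: float = 2.0,
    threshold: float | None = None,
) -> GLIImage:
    """Aggregate a binary cell mask into a GLI grid.

    The field edge must be an integer number of pixels; otherwise the caller
    is told to resample.  Partial fields at the right/bottom edge are
    discarded.
    """
    mask = np.asarray(mask, dtype=bool)
    f_float = field_size_um / resolution_um_per_px
    f = int(round(f_float))
    if f <= 0 or abs(f_float - f) > 1e-9:
        raise ValueError(
            f"field edge {field_size_um} um is {f_float} px at "
            f"{resolution_um_per_px} um/px; resample the image so the field "
            "is an integer number of pixels"
        )
    h, w = mask.shape
    nh, nw = h // f, w // f
    if nh == 0 or nw == 0:
        raise ValueError("image smaller than one measuring field")
    cropped = mask[: nh * f, : nw * f]
    values = cropped.reshape(nh, f, nw, f).mean(axis=(1, 3))
    return GLIImage(
        values=values,
        field_size_um=field_size_um,
        resolution_um_per_px=resolution_um_per_px,
        threshold=threshold,
    )


def save_gli(gli: GLIImage, path: str | Path) -> None:
    """32-bit float TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, gli.values.astype(np.float32))
    meta = {
        "field_size_um": gli.field_size_um,
        "resolution_um_per_px": gli.resolution_um_per_px,
        "threshold": gli.threshold,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_gli(path: str | Path) -> GLIImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return GLIImage(values=tifffile.imread(path).astype(float), **meta)
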
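"""Loading, calibration and canonical orientation of single-molar images.

Input images are photographs (background already removed: dark tooth on a
near-white or transparent background) or line drawings from the literature.
The canonical pose places the anterior part of the molar on the left and the
buccal (labial) side at the bottom of the screen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import BackgroundNotCleanedError, ValidationError

__all__ = ["OcclusalImage", "load_specimen_image", "normalize_orientation"]

#: fixed binarization threshold for line drawings (near-binary input)
DRAWING_THRESHOLD = 0.5


@dataclass(frozen=True)
class OcclusalImage:
    """A calibrated raster of one molar.

    Attributes
    ----------
    image : (H, W) float array in [0, 1]; 1 is the white background.
    foreground : (H, W) boolean mask of the (dark) tooth.
    scale : mm per pixel, > 0.
    source_kind : ``"photo"`` or ``"drawing"``.
    oriented : whether the canonical pose has been asserted/applied.
    """

    image: np.ndarray
    foreground: np.ndarray
    scale: float
    source_kind: str
    oriented: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def _binarize(grey: np.ndarray, source_kind: str, invert: bool) -> np.ndarray:
    """Foreground mask: dark pixels on a light background (or inverted)."""
    if invert:
        grey = 1.0 - grey
    if source_kind == "photo":
        # Otsu needs a bimodal histogram; an (almost) blank image has none
        if grey.min() > 0.95 or np.ptp(grey) < 1e-3:
            return np.zeros(grey.shape, dtype=bool)
        thr = threshold_otsu(grey)
    else:
        thr = DRAWING_THRESHOLD
    return grey < thr


def load_specimen_image(
    path: str | Path,
    scale: float,
    source_kind: str = "photo",
    invert: bool = False,
) -> OcclusalImage:
    """Load and calibrate a background-cleaned molar image.

    Alpha channels are flattened against white; colour is converted to
    greyscale.  After binarization a photograph must contain exactly one
    connected foreground component (the tooth).  A drawing may additionally
    contain small satellite components — the cement areas drawn inside the
    re-entrant folds — but no second component of comparable size.

    Raises
    ------
    ValidationError
        scale <= 0 or unknown source kind.
    BackgroundNotCleanedError
        zero or more than one foreground component.
    OSError
        unreadable or undecodable file.
    """
    if scale <= 0:
        raise ValidationError(f"scale must be positive mm/px, got {scale}")
    if source_kind not in ("photo", "drawing"):
        raise ValidationError(f"source_kind must be 'photo' or 'drawing', got {source_kind!r}")

    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA"):
            background = Image.new("RGBA", im.size, (255, 255, 255, 255))
            im = Image.alpha_composite(background, im.convert("RGBA"))
        grey = np.asarray(im.convert("F"), dtype=float)
    if grey.max() > 1.0:
        grey /= 255.0
    grey = np.clip(grey, 0.0, 1.0)

    fg = _binarize(grey, source_kind, invert)
    lab = cc_label(fg, connectivity=2)
    n = int(lab.max())
    if n == 0:
        raise BackgroundNotCleanedError("background not cleaned: no foreground found")
    if source_kind == "photo":
        if n > 1:
            raise BackgroundNotCleanedError(
                f"background not cleaned: {n} foreground components (expected 1)"
            )
    else:
        # drawings legitimately contain cement blobs as satellite components
        # inside the re-entrant folds; a second component of comparable size,
        # however, means the background was not cleaned
        sizes = np.sort(np.bincount(lab.ravel())[1:])[::-1]
        if len(sizes) > 1 and sizes[1] >= 0.5 * sizes[0]:
            raise BackgroundNotCleanedError(
                "background not cleaned: multiple large foreground components"
            )
    return OcclusalImage(image=grey, foreground=fg, scale=float(scale), source_kind=source_kind)


def normalize_orientation(
    img: OcclusalImage,
    rotation_deg: float = 0.0,
    flip_horizontal: bool = False,
    flip_vertical: bool = False,
) -> OcclusalImage:
    """Rotate/flip the image into the canonical pose and mark it oriented.

    Rotation is about the image centre, counter-clockwise in screen
    coordinates, with the canvas enlarged to avoid clipping.  Flips are
    applied after the rotation.  Photographs are resampled bilinearly;
    drawings use nearest-neighbour so strokes stay thin and binary.  The
    mm-per-px scale is unchanged (rotation is rigid).
    """
    grey = img.image
    if rotation_deg % 360 != 0:
        order = 1 if img.source_kind == "photo" else 0
        grey = ndimage.rotate(
            grey, rotation_deg, reshape=True, order=order, mode="constant", cval=1.0
        )
        grey = np.clip(grey, 0.0, 1.0)
    if flip_horizontal:
        grey = grey[:, ::-1]
    if flip_vertical:
        grey = grey[::-1, :]
    fg = _binarize(grey, img.source_kind, invert=False)
    return replace(img, image=np.ascontiguousarray(grey), foreground=fg, oriented=True)
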
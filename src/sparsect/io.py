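"""File output for phantoms, masks, and reconstructions.

HU images go out two ways: raw HU as NIfTI (via nibabel, spacing recorded in
the affine) and display-windowed 16-bit PNG; boolean masks as 8-bit PNG.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio
import nibabel as nib

from .phantoms import ImageHU


def write_nifti(img: ImageHU | np.ndarray, path, spacing_mm: float = 1.0) -> None:
    if isinstance(img, ImageHU):
        px, spacing_mm = img.pixels, img.spacing_mm
    else:
        px = np.asarray(img, dtype=float)
    affine = np.diag([spacing_mm, spacing_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(px.astype(np.float32), affine), str(path))


def read_nifti(path) -> ImageHU:
    im = nib.load(str(path))
    data = np.asarray(im.dataobj, dtype=float)
    spacing = float(abs(im.affine[0, 0])) or 1.0
    return ImageHU(np.squeeze(data), spacing_mm=spacing)


def write_png_windowed(img: ImageHU | np.ndarray, path,
                       window: tuple[float, float] = (-1024.0, 976.0)) -> None:
    """16-bit PNG after clipping HU to the display window."""
    px = img.pixels if isinstance(img, ImageHU) else np.asarray(img, dtype=float)
    lo, hi = window
    scaled = (np.clip(px, lo, hi) - lo) / (hi - lo)
    iio.imwrite(str(path), np.round(scaled * 65535).astype(np.uint16))


def write_mask_png(mask: np.ndarray, path) -> None:
    iio.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))
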
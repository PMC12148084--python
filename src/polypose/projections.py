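"""Reading and writing 2D projection images.

Rendered X-rays are negative log-intensities (line integrals, float).  The
native on-disk format here is float TIFF; 16-bit PNG/TIFF inputs are rescaled
to [0, 1] (their intensity scale is arbitrary for a correlation-based
similarity), and 2D NIfTI is accepted as-is.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_image", "write_image"]


def read_image(path) -> np.ndarray:
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {data.shape}: {path}")
        return np.asarray(data, dtype=float)
    if suffix.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(str(path))
    elif suffix.endswith(".png"):
        import imageio.v3 as iio

        data = iio.imread(str(path))
    else:
        raise ValueError(f"unsupported image format: {path}")
    data = np.squeeze(np.asarray(data))
    if data.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {data.shape}: {path}")
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(float) / float(np.iinfo(data.dtype).max)
    return data.astype(float)


def write_image(image: np.ndarray, path) -> None:
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))
    elif suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), np.eye(4)), str(path))
    elif suffix.endswith(".png"):
        import imageio.v3 as iio

        arr = np.asarray(image, dtype=float)
        lo, hi = arr.min(), arr.max()
        scaled = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
        iio.imwrite(str(path), (scaled * 65535).astype(np.uint16))
    else:
        raise ValueError(f"unsupported image format: {path}")
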
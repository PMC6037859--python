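"""NIfTI-1 serialization for simulated volumes and statistic maps.

Synthetic volumes use an identity affine, so voxel indices stand in for
world coordinates throughout the pipeline.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .synthetic import BoldRun

__all__ = ["save_volume", "load_volume", "save_bold_run", "load_bold_run"]


def save_volume(data: np.ndarray, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), affine=np.eye(4))
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_bold_run(run: BoldRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr_s))
    nib.save(img, str(path))


def load_bold_run(path) -> BoldRun:
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3])
    return BoldRun(data=np.asarray(img.get_fdata()), tr_s=tr)
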
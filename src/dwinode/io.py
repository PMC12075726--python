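"""File-format plumbing: NIfTI volumes, b-value tables, cohort CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import ParameterMap
from .models import BValueProtocol

__all__ = [
    "read_bvalues",
    "load_volume",
    "save_parameter_map",
    "save_volume4d",
]


def read_bvalues(path, units: str = "auto", **timing) -> BValueProtocol:
    """Read a b-value table (whitespace text or a JSON list) into a
    protocol.

    ``units``: ``'s/mm2'``, ``'ms/um2'`` or ``'auto'`` (values above 50
    are taken as s/mm^2 and divided by 1000 into canonical ms/um^2).
    Extra keyword arguments (delta, Delta, gamma) pass through to
    :class:`BValueProtocol`.
    """
    text = Path(path).read_text().strip()
    if text.startswith("["):
        values = np.asarray(json.loads(text), dtype=float)
    else:
        values = np.asarray(text.split(), dtype=float)
    if units == "auto":
        units = "s/mm2" if values.max() > 50.0 else "ms/um2"
    if units == "s/mm2":
        values = values / 1000.0
    elif units != "ms/um2":
        raise ValueError(f"unknown b-value units {units!r}")
    return BValueProtocol(b_values=tuple(values), **timing)


def load_volume(path):
    """Load a NIfTI volume; returns (float ndarray, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def save_parameter_map(pmap: ParameterMap, path) -> None:
    """Write one parameter map as float32 NIfTI-1, NaN outside the
    validity mask, preserving the source affine."""
    data = np.where(pmap.valid, pmap.data, np.nan).astype(np.float32)
    nib.save(nib.Nifti1Image(data, pmap.affine), str(path))


def save_volume4d(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
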
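"""Core in-memory containers shared across the pipeline.

Voxel data live in dense numpy arrays; scan-level and subject-level
metadata live in pandas DataFrames.  A single binary gray-matter mask and
a single voxel-to-mm affine are shared by every volume in an analysis.
Vectors "over the mask" are ordered by ``np.flatnonzero(mask)`` of the
C-raveled grid, and that ordering is used consistently by every module.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

SCAN_COLUMNS = ["subject", "group", "condition", "run", "timepoint"]
CONDITIONS = ("LEARN", "MOVE", "REST")


def mask_indices(mask: np.ndarray) -> np.ndarray:
    """Flat (C-order) indices of in-mask voxels; the canonical voxel order."""
    return np.flatnonzero(np.asarray(mask, dtype=bool).ravel())


def flatten_in_mask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract in-mask voxels of one volume (3-D) or a stack (4-D)."""
    values = np.asarray(values, dtype=float)
    idx = mask_indices(mask)
    if values.ndim == mask.ndim:
        return values.ravel()[idx]
    return values.reshape(values.shape[0], -1)[:, idx]


def unflatten_to_grid(flat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Place an in-mask vector back on the 3-D grid (zeros outside)."""
    out = np.zeros(mask.size, dtype=float)
    out[mask_indices(mask)] = np.asarray(flat, dtype=float)
    return out.reshape(mask.shape)


@dataclasses.dataclass
class ScanSet:
    """A stack of registered scans plus per-scan labels.

    Parameters
    ----------
    volumes : (n_scans, nx, ny, nz) array
    index : DataFrame with columns subject, group, condition, run, timepoint
    mask : (nx, ny, nz) boolean array (shared gray-matter mask)
    affine : (4, 4) voxel-to-mm map
    """

    volumes: np.ndarray
    index: pd.DataFrame
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be a 4-D (n_scans, nx, ny, nz) array")
        if self.volumes.shape[1:] != self.mask.shape:
            raise ValueError("volume grid does not match mask grid")
        if not self.mask.any():
            raise ValueError("mask is empty")
        missing = [c for c in SCAN_COLUMNS if c not in self.index.columns]
        if missing:
            raise ValueError(f"scan index missing columns: {missing}")
        if len(self.index) != self.volumes.shape[0]:
            raise ValueError("index length does not match number of volumes")
        self.index = self.index.reset_index(drop=True)

    @property
    def n_scans(self) -> int:
        return self.volumes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def select(self, **labels) -> "ScanSet":
        """Subset scans by label equality, e.g. ``select(condition="MOVE")``."""
        keep = np.ones(self.n_scans, dtype=bool)
        for col, val in labels.items():
            keep &= (self.index[col] == val).to_numpy()
        return ScanSet(self.volumes[keep], self.index.loc[keep], self.mask, self.affine)

    def in_mask(self) -> np.ndarray:
        """(n_scans, n_mask_voxels) view of the in-mask data."""
        return flatten_in_mask(self.volumes, self.mask)

    # ---- NIfTI round trip -------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        """Write one NIfTI per scan plus the shared mask and the scan table."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine),
                 path / "mask.nii.gz")
        names = []
        for i, row in self.index.iterrows():
            name = (f"sub-{row.subject}_cond-{row.condition}"
                    f"_run-{int(row.run)}_tp-{int(row.timepoint)}.nii.gz")
            nib.save(nib.Nifti1Image(self.volumes[i], self.affine), path / name)
            names.append(name)
        table = self.index.copy()
        table["filename"] = names
        table.to_csv(path / "scans.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "ScanSet":
        path = Path(path)
        table = pd.read_csv(path / "scans.tsv", sep="\t")
        mask_img = nib.load(path / "mask.nii.gz")
        mask = np.asarray(mask_img.dataobj) > 0
        vols = np.stack([np.asarray(nib.load(path / f).dataobj, dtype=float)
                         for f in table["filename"]])
        return cls(vols, table[SCAN_COLUMNS], mask, mask_img.affine)


@dataclasses.dataclass
class Pattern:
    """A voxel-weight map (network topography) over the shared mask.

    ``weights`` is a vector over in-mask voxels in canonical order.
    Derived patterns are kept at unit Euclidean norm; sign conventions are
    applied by the deriving code, not here.
    """

    weights: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.weights.shape != (int(self.mask.sum()),):
            raise ValueError("weights length must equal number of in-mask voxels")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.weights))

    def to_volume(self) -> np.ndarray:
        return unflatten_to_grid(self.weights, self.mask)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.to_volume(), self.affine), Path(path))

    @classmethod
    def from_nifti(cls, path: str | Path, mask: np.ndarray) -> "Pattern":
        img = nib.load(Path(path))
        vol = np.asarray(img.dataobj, dtype=float)
        return cls(flatten_in_mask(vol, mask), mask, img.affine)

    def cosine(self, other: "Pattern") -> float:
        """Cosine similarity between two unit-direction weight maps."""
        a, b = self.weights, other.weights
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


@dataclasses.dataclass
class DataMatrix:
    """Rows = subtraction images, columns = in-mask voxels."""

    X: np.ndarray
    index: pd.DataFrame  # columns: subject, run, timepoint
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (rows x voxels)")
        if self.X.shape[1] != int(np.asarray(self.mask, bool).sum()):
            raise ValueError("column count must equal in-mask voxel count")
        if len(self.index) != self.X.shape[0]:
            raise ValueError("index length does not match row count")
        if not np.isfinite(self.X).all():
            raise ValueError("data matrix contains non-finite entries")
        self.index = self.index.reset_index(drop=True)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.index["subject"]))


def save_subject_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), sep="\t", index=False)


def load_subject_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def ensure_burden(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``burden`` column (max cohort YTO minus YTO) if absent.

    Burden increases as a gene carrier approaches predicted clinical onset;
    subjects without a YTO (e.g. non-carrier controls) get burden 0.
    """
    table = subject_table.copy()
    if "burden" in table.columns:
        return table
    if "yto" not in table.columns:
        raise ValueError("subject table needs a 'yto' or 'burden' column")
    yto = pd.to_numeric(table["yto"], errors="coerce")
    ref = yto.max()
    table["burden"] = (ref - yto).fillna(0.0)
    return table


_SCAN_NAME_RE = re.compile(
    r"sub-(?P<subject>[^_]+)_cond-(?P<condition>[A-Z]+)_run-(?P<run>\d+)_tp-(?P<timepoint>\d+)"
)


def parse_scan_name(name: str) -> dict:
    m = _SCAN_NAME_RE.search(name)
    if m is None:
        raise ValueError(f"cannot parse scan labels from filename {name!r}")
    d = m.groupdict()
    d["run"] = int(d["run"])
    d["timepoint"] = int(d["timepoint"])
    return d
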
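"""In-memory containers and on-disk formats for DWI volumes and ROI maps.

Volumes are NIfTI-1 (via nibabel) with a plain-text gradient-table sidecar:
one row per volume, whitespace-separated columns

    kind f_or_delta param2 n_cycles b gx gy gz

where ``kind`` is PG, OG or B0; ``f_or_delta`` is the oscillating frequency
(Hz) for OG or the pulse duration δ (ms) for PG; ``param2`` is the pulse
separation Δ (ms) for PG (0 otherwise); ``b`` is in ms/µm². The reader and
writer round-trip the table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["DWIDataset", "ROILabelMap", "gradient_table_rows",
           "read_gradient_table", "write_gradient_table"]

GRADIENT_COLUMNS = ["kind", "f_or_delta", "param2", "n_cycles", "b",
                    "gx", "gy", "gz"]


def gradient_table_rows(*, n_b0: int, directions: np.ndarray, b: float,
                        conditions: list[dict]) -> pd.DataFrame:
    """Build a gradient table for a multi-condition protocol.

    ``conditions`` is a list of dicts such as ``{"kind": "PG", "delta": 5,
    "Delta": 20}`` or ``{"kind": "OG", "freq": 50, "n_cycles": 1}``; every
    condition gets ``n_b0`` b0 volumes followed by one DWI volume per
    direction.
    """
    rows = []
    for cond in conditions:
        kind = cond["kind"].upper()
        if kind == "PG":
            p1, p2, nc = cond["delta"], cond["Delta"], 0
        elif kind == "OG":
            p1, p2, nc = cond["freq"], 0.0, int(cond["n_cycles"])
        else:
            raise ValueError(f"unknown condition kind {kind!r}")
        for _ in range(n_b0):
            rows.append(["B0", p1, p2, nc, 0.0, 0.0, 0.0, 0.0])
        for g in directions:
            rows.append([kind, p1, p2, nc, b, g[0], g[1], g[2]])
    return pd.DataFrame(rows, columns=GRADIENT_COLUMNS)


def condition_labels(gtab: pd.DataFrame) -> pd.Series:
    """Condition label per volume: "PG" or "OG<freq>"; b0 rows inherit the
    condition they are interleaved with (by parameters)."""
    def label(row):
        if row["kind"] == "PG" or (row["kind"] == "B0" and row["n_cycles"] == 0):
            return "PG"
        return f"OG{row['f_or_delta']:g}"
    return gtab.apply(label, axis=1)


def write_gradient_table(gtab: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# " + " ".join(GRADIENT_COLUMNS) + "\n")
        for _, row in gtab.iterrows():
            fh.write(
                f"{row['kind']} {row['f_or_delta']:.17g} {row['param2']:.17g} "
                f"{int(row['n_cycles'])} {row['b']:.17g} "
                f"{row['gx']:.17g} {row['gy']:.17g} {row['gz']:.17g}\n")


def read_gradient_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=GRADIENT_COLUMNS, float_precision="round_trip")
    df["n_cycles"] = df["n_cycles"].astype(int)
    return df


@dataclass
class DWIDataset:
    """4-D diffusion-weighted dataset with its gradient table."""

    data: np.ndarray  # (x, y, z, n_volumes)
    gtab: pd.DataFrame
    voxel_size: tuple[float, float, float]  # mm
    mask: np.ndarray | None = None  # (x, y, z) bool

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, volume)")
        if len(self.gtab) != self.data.shape[3]:
            raise ValueError("gradient table length must match volume count")
        if self.mask is not None and self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask grid does not match data grid")

    @property
    def conditions(self) -> list[str]:
        """Distinct diffusion conditions in acquisition order."""
        labels = condition_labels(self.gtab)
        return list(dict.fromkeys(labels))

    def volumes_for(self, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """(b0 volume indices, DWI volume indices) of one condition."""
        labels = condition_labels(self.gtab)
        sel = labels == condition
        b0 = np.flatnonzero(sel & (self.gtab["b"] == 0))
        dwi = np.flatnonzero(sel & (self.gtab["b"] > 0))
        return b0, dwi

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])

    def save(self, stem) -> None:
        """Write ``<stem>.nii`` plus ``<stem>.grad`` sidecar."""
        stem = Path(stem)
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine),
                 str(stem.with_suffix(".nii")))
        write_gradient_table(self.gtab, stem.with_suffix(".grad"))

    @classmethod
    def load(cls, stem) -> "DWIDataset":
        stem = Path(stem)
        img = nib.load(str(stem.with_suffix(".nii")))
        data = np.asarray(img.dataobj, dtype=float)
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        gtab = read_gradient_table(stem.with_suffix(".grad"))
        return cls(data=data, gtab=gtab, voxel_size=vox)


@dataclass
class ROILabelMap:
    """Integer-labelled volume with a label→name table."""

    labels: np.ndarray  # (x, y, z) int
    names: dict[int, str]
    voxel_size: tuple[float, float, float]  # mm

    def __post_init__(self):
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("ROI names must be unique")
        if (np.asarray(self.labels) < 0).any():
            raise ValueError("labels must be non-negative")

    @property
    def voxel_volume(self) -> float:
        """Physical voxel volume, mm³."""
        return float(np.prod(self.voxel_size))

    def volume_of(self, label: int) -> float:
        """ROI volume in mm³."""
        return float(np.count_nonzero(self.labels == label)) * self.voxel_volume

    def save(self, path) -> None:
        affine = np.diag(list(self.voxel_size) + [1.0])
        img = nib.Nifti1Image(self.labels.astype(np.int16), affine)
        img.header["descrip"] = ";".join(
            f"{k}={v}" for k, v in sorted(self.names.items())).encode()[:80]
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "ROILabelMap":
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(int)
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        desc = img.header["descrip"].tobytes().decode().rstrip("\x00")
        names = {}
        for item in desc.split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                names[int(k)] = v
        return cls(labels=labels, names=names, voxel_size=vox)
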
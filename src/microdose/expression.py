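"""Gene x cell count matrices and 10x-style MatrixMarket trio interchange."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

__all__ = ["ExpressionGroup", "write_tenx_trio", "read_tenx_trio", "group_dirname"]


@dataclass
class ExpressionGroup:
    """Gene x cell non-negative integer count matrix tagged with a dose label.

    ``dose_mGy = 0`` marks the unirradiated control group.
    """

    gene_ids: np.ndarray
    barcodes: np.ndarray
    counts: np.ndarray  # dense (n_genes, n_cells); sparse inputs are densified
    dose_mGy: float
    gene_names: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d gene x cell matrix")
        if self.counts.shape != (self.gene_ids.size, self.barcodes.size):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{self.gene_ids.size} genes x {self.barcodes.size} barcodes"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts)
            if not np.allclose(self.counts, as_int):
                raise ValueError("counts must be integral")
            self.counts = as_int.astype(np.int64)
        if len(set(self.gene_ids)) != self.gene_ids.size:
            raise ValueError("gene_ids must be unique")
        if self.gene_names is None:
            self.gene_names = self.gene_ids.copy()
        else:
            self.gene_names = np.asarray(self.gene_names, dtype=object)
            if self.gene_names.size != self.gene_ids.size:
                raise ValueError("gene_names must match gene_ids in length")

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_cells(self) -> int:
        return self.barcodes.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionGroup):
            return NotImplemented
        return (
            self.dose_mGy == other.dose_mGy
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.counts, other.counts)
        )


def group_dirname(dose_mGy: float) -> str:
    """Canonical per-group directory name, e.g. ``group_100mGy``."""
    if float(dose_mGy).is_integer():
        return f"group_{int(dose_mGy)}mGy"
    return f"group_{dose_mGy}mGy"


def write_tenx_trio(group: ExpressionGroup, directory) -> None:
    """Write matrix.mtx (MatrixMarket coordinate integer), features.tsv
    (gene_id, gene_name) and barcodes.tsv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sparse.coo_matrix(group.counts)
    sio.mmwrite(str(directory / "matrix.mtx"), coo, field="integer")
    pd.DataFrame(
        {"gene_id": group.gene_ids, "gene_name": group.gene_names}
    ).to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(group.barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_tenx_trio(directory, dose_mGy: Optional[float] = None) -> ExpressionGroup:
    """Read a 10x trio directory back into an :class:`ExpressionGroup`.

    The dose label is parsed from a ``group_<dose>mGy`` directory name when
    not given explicitly.
    """
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    features = directory / "features.tsv"
    barcodes = directory / "barcodes.tsv"
    for p in (mtx, features, barcodes):
        if not p.exists():
            raise FileNotFoundError(f"missing 10x trio file: {p}")
    mat = sio.mmread(str(mtx))
    counts = np.asarray(sparse.coo_matrix(mat).todense())
    feat = pd.read_csv(features, sep="\t", header=None, dtype=str)
    bc = pd.read_csv(barcodes, sep="\t", header=None, dtype=str)
    if counts.shape[0] != len(feat) or counts.shape[1] != len(bc):
        raise ValueError(
            f"matrix {counts.shape} does not match {len(feat)} features "
            f"x {len(bc)} barcodes"
        )
    if dose_mGy is None:
        m = re.fullmatch(r"group_([0-9.]+)mGy", directory.name)
        if m is None:
            raise ValueError(
                f"cannot infer dose from directory name {directory.name!r}; "
                "pass dose_mGy explicitly"
            )
        dose_mGy = float(m.group(1))
    return ExpressionGroup(
        gene_ids=feat[0].to_numpy(object),
        barcodes=bc[0].to_numpy(object),
        counts=counts,
        dose_mGy=float(dose_mGy),
        gene_names=feat[1].to_numpy(object) if feat.shape[1] > 1 else None,
    )
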
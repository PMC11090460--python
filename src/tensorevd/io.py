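"""File round-tripping: kernels, ID maps, phenotype tables, EVD artifacts.

Delimited-text formats (comma or tab, sniffed on read) carry labels in a
header row / first column; large objects can also round-trip through a
NumPy ``.npz`` container.  Phenotype tables may carry ``#``-prefixed
provenance header lines recording the generating seed and parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EVDResult, Kernel

__all__ = [
    "read_kernel",
    "write_kernel",
    "read_idmap",
    "write_idmap",
    "read_phenotypes",
    "write_phenotypes",
    "save_kernel_npz",
    "load_kernel_npz",
    "save_evd",
    "load_evd",
    "write_evd_summary",
]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if line.count("\t") >= line.count(",") else ","
    return ","


def read_kernel(path) -> Kernel:
    """Read a labeled square matrix from delimited text (header row + label column)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, comment="#")
    return Kernel(values=df.to_numpy(dtype=float), labels=df.columns.to_numpy(dtype=str))


def write_kernel(kernel: Kernel, path, sep: str = "\t") -> None:
    df = pd.DataFrame(kernel.values, index=kernel.labels, columns=kernel.labels)
    df.to_csv(path, sep=sep)


def read_idmap(path) -> pd.DataFrame:
    """Read per-observation IDs: delimited text with required columns id1, id2."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", dtype=str)
    missing = {"id1", "id2"} - set(df.columns)
    if missing:
        raise ValueError(f"ID file {path} lacks required column(s): {sorted(missing)}")
    return df[["id1", "id2"]]


def write_idmap(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df[["id1", "id2"]].to_csv(path, sep=sep, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Read an observation table with columns id1, id2, y (``#`` headers skipped)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    missing = {"id1", "id2", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file {path} lacks required column(s): {sorted(missing)}")
    df["id1"] = df["id1"].astype(str)
    df["id2"] = df["id2"].astype(str)
    df["y"] = df["y"].astype(float)
    return df


def write_phenotypes(df: pd.DataFrame, path, provenance: dict | None = None, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write("# " + json.dumps(provenance, sort_keys=True) + "\n")
        df.to_csv(fh, sep=sep, index=False)


def save_kernel_npz(kernel: Kernel, path) -> None:
    np.savez_compressed(path, values=kernel.values, labels=kernel.labels)


def load_kernel_npz(path) -> Kernel:
    with np.load(path, allow_pickle=False) as z:
        return Kernel(values=z["values"], labels=z["labels"].astype(str))


def save_evd(evd: EVDResult, path) -> None:
    """Store an EVD basis in a ``.npz`` container."""
    np.savez_compressed(
        path,
        vectors=evd.vectors,
        values=evd.values,
        total_variance=np.array(evd.total_variance),
        alpha_requested=np.array(evd.alpha_requested),
        alpha_achieved=np.array(evd.alpha_achieved),
        source_indices=evd.source_indices,
    )


def load_evd(path) -> EVDResult:
    with np.load(path, allow_pickle=False) as z:
        return EVDResult(
            vectors=z["vectors"],
            values=z["values"],
            total_variance=float(z["total_variance"]),
            alpha_requested=float(z["alpha_requested"]),
            alpha_achieved=float(z["alpha_achieved"]),
            source_indices=z["source_indices"],
        )


def write_evd_summary(evd: EVDResult, path, sep: str = "\t") -> None:
    """Delimited eigenvalue summary: index, value, cumulative fraction, source (i, j)."""
    csum = np.cumsum(evd.values)
    total = evd.total_variance if evd.total_variance > 0 else 1.0
    if len(evd.source_indices):
        i_src = evd.source_indices[:, 0]
        j_src = evd.source_indices[:, 1]
    else:
        i_src = np.full(len(evd.values), -1)
        j_src = np.full(len(evd.values), -1)
    df = pd.DataFrame(
        {
            "index": np.arange(1, len(evd.values) + 1),
            "value": evd.values,
            "cumulative_fraction": csum / total,
            "i": i_src,
            "j": j_src,
        }
    )
    df.to_csv(path, sep=sep, index=False)
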
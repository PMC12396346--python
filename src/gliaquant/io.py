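"""Plain-text readers and writers for the pipeline inputs and outputs.

Expression matrices travel as MatrixMarket triplets (matrix.mtx + genes.tsv +
barcodes.tsv) or dense TSV, with a cells.tsv metadata table; signatures as
GMT or one-gene-per-line lists; traces, puncta, cell records and spheroid
tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .photometry import PhotometryTrace
from .puncta import PunctaSet
from .sc_state import ExpressionMatrix

META_COLUMNS = ("cell_id", "sample", "platform", "malignant")


def write_expression(m: ExpressionMatrix, outdir, extra_cell_columns=None) -> None:
    """Write matrix.mtx (genes x cells), genes.tsv, barcodes.tsv, cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(m.values))
    pd.Series(m.gene_ids).to_csv(outdir / "genes.tsv", sep="\t",
                                 index=False, header=False)
    pd.Series(m.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                 index=False, header=False)
    meta = pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "sample": m.sample_of_cell,
            "platform": [m.platform_of_sample[s] for s in m.sample_of_cell],
            "malignant": m.malignant,
        }
    )
    if extra_cell_columns is not None:
        for name, vals in extra_cell_columns.items():
            meta[name] = np.asarray(vals)
    meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_expression(matrix_path, meta_path=None, genes_path=None,
                    barcodes_path=None, unit: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix from an MTX directory/file or a dense TSV.

    For MTX input, ``genes.tsv``/``barcodes.tsv``/``cells.tsv`` default to
    siblings of the matrix file. Dense TSV input has genes in rows (index)
    and cell ids as column headers, with metadata in ``meta_path``.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.is_dir():
        matrix_path = matrix_path / "matrix.mtx"
    if matrix_path.suffix == ".mtx":
        values = np.asarray(spio.mmread(matrix_path).todense(), dtype=float)
        folder = matrix_path.parent
        genes_path = Path(genes_path or folder / "genes.tsv")
        barcodes_path = Path(barcodes_path or folder / "barcodes.tsv")
        meta_path = Path(meta_path or folder / "cells.tsv")
        gene_ids = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).to_numpy()
        cell_ids = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).to_numpy()
    else:
        dense = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values = dense.to_numpy(dtype=float)
        gene_ids = dense.index.astype(str).to_numpy()
        cell_ids = dense.columns.astype(str).to_numpy()
        if meta_path is None:
            raise ValueError("dense TSV input requires a cell metadata table")
    meta = pd.read_csv(meta_path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cell metadata lacks columns {missing}")
    meta = meta.set_index("cell_id").loc[list(cell_ids)]
    platform_of_sample = (
        meta.groupby("sample")["platform"].first().to_dict()
    )
    malignant = meta["malignant"].astype(str).str.lower().isin(("true", "1")).to_numpy()
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        sample_of_cell=meta["sample"].astype(str).to_numpy(),
        platform_of_sample=platform_of_sample,
        malignant=malignant,
        unit=unit,
    )


def write_gmt(signatures: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, name, *genes]) + "\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_trace(trace: PhotometryTrace, path) -> None:
    pd.DataFrame({"time_s": trace.t, "F": trace.F}).to_csv(path, index=False)


def read_trace(path, baseline_window=None, fs=None) -> PhotometryTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "F"):
        if col not in df.columns:
            raise ValueError(f"trace CSV lacks column {col!r}")
    return PhotometryTrace(
        t=df["time_s"].to_numpy(float),
        F=df["F"].to_numpy(float),
        fs=fs,
        baseline_window=baseline_window,
    )


def write_puncta(sets, path) -> None:
    """Write one or more PunctaSets to a channel-tagged CSV."""
    frames = []
    for s in ([sets] if isinstance(sets, PunctaSet) else list(sets)):
        frames.append(
            pd.DataFrame(
                {
                    "channel": s.channel,
                    "x_um": s.coords[:, 0],
                    "y_um": s.coords[:, 1],
                    "z_um": s.coords[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_puncta(path, channel: str | None = None) -> PunctaSet:
    df = pd.read_csv(path)
    for col in ("channel", "x_um", "y_um", "z_um"):
        if col not in df.columns:
            raise ValueError(f"puncta CSV lacks column {col!r}")
    if channel is not None:
        df = df[df["channel"] == channel]
        label = channel
    else:
        labels = df["channel"].unique()
        if len(labels) > 1:
            raise ValueError(
                f"CSV holds channels {list(labels)}; pass channel= to pick one"
            )
        label = labels[0] if len(labels) else ""
    return PunctaSet(
        channel=str(label),
        coords=df[["x_um", "y_um", "z_um"]].to_numpy(float),
    )


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
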
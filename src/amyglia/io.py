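"""Readers and writers for the standard interchange formats.

Gene sets travel as GMT (name, description, tab-separated members), ranked
lists as two-column RNK files, bulk counts and metadata as TSV, single-cell
counts as Matrix Market MTX with 10x-style features.tsv/barcodes.tsv
(1-based indices), and ground truth / test summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

FLOAT_FMT = "%.10g"


def write_gmt(sets: dict, path, description: str = "amyglia") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sets[name])
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_rnk(ranked: pd.Series, path) -> None:
    ranked.to_csv(path, sep="\t", header=False, float_format=FLOAT_FMT)


def read_rnk(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "metric"])
    return df.set_index("gene")["metric"].sort_values(ascending=False)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_samples_tsv(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").to_csv(path, sep="\t")


def read_samples_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_10x(adata: ad.AnnData, outdir) -> None:
    """matrix.mtx + features.tsv + barcodes.tsv (genes x cells on disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    m = sparse.csr_matrix(x) if not sparse.issparse(x) else x
    spio.mmwrite(str(outdir / "matrix.mtx"), m.T.astype(int))
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    adata.obs.rename_axis("barcode").to_csv(outdir / "cells.tsv", sep="\t")


def read_10x(indir) -> ad.AnnData:
    indir = Path(indir)
    m = spio.mmread(str(indir / "matrix.mtx")).tocsr().T
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    adata = ad.AnnData(
        X=m,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
    cells = indir / "cells.tsv"
    if cells.exists():
        meta = pd.read_csv(cells, sep="\t", index_col="barcode")
        adata.obs = meta.loc[adata.obs_names]
    return adata


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
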
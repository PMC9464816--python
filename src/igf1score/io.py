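"""File formats: count matrices, signed gene sets, metadata, size factors.

Conventions (stated in every header comment written):

* matrices are genes-in-rows, samples-in-columns; TSV/CSV carry the
  gene identifier in the first column and sample identifiers in the
  header; MTX is the Matrix Market triplet with side files listing the
  gene and sample identifiers one per line;
* signed gene sets are JSON ``{gene: +1/-1}`` or a GMT pair of sets
  named ``<NAME>_UP`` / ``<NAME>_DN`` (GMT itself has no sign channel);
* metadata TSV columns are typed by header suffix ``:num``, ``:bool``,
  ``:cat``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .de import SignedGeneSet
from .preprocess import validate_counts

__all__ = [
    "read_counts",
    "write_counts",
    "read_signature",
    "write_signature",
    "read_metadata",
    "write_metadata",
    "read_size_factors",
    "write_size_factors",
]

_HEADER_COMMENT = "# genes in rows, samples in columns"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_counts(path, format: str | None = None) -> pd.DataFrame:
    """Read a genes × samples count matrix (TSV, CSV or MTX triplet).

    For MTX, ``<stem>.genes.txt`` and ``<stem>.samples.txt`` next to the
    matrix file provide the identifiers. Duplicate identifiers and
    negative or fractional entries are rejected with coordinates.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, comment="#", index_col=0)
        df.index.name = "gene"
        df.columns.name = "sample"
    elif fmt == "mtx":
        mat = mmread(path).tocsr().toarray()
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().splitlines()
        samples = Path(f"{stem}.samples.txt").read_text().splitlines()
        genes = [g for g in genes if g and not g.startswith("#")]
        samples = [s for s in samples if s and not s.startswith("#")]
        if mat.shape != (len(genes), len(samples)):
            raise ValueError(
                f"MTX shape {mat.shape} does not match {len(genes)} genes x {len(samples)} samples"
            )
        df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                          columns=pd.Index(samples, name="sample"))
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    validate_counts(df, name=str(path))
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path, format: str | None = None, *,
                 comment: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        with open(path, "w") as fh:
            fh.write(_HEADER_COMMENT + "\n")
            if comment:
                fh.write(f"# {comment}\n")
            counts.to_csv(fh, sep=sep)
    elif fmt == "mtx":
        mmwrite(path, csr_matrix(counts.to_numpy()))
        stem = path.with_suffix("")
        Path(f"{stem}.genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_signature(path, format: str | None = None) -> SignedGeneSet:
    """Read a signed gene set from JSON ``{gene: ±1}`` or a GMT pair."""
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "json"
    if format == "json":
        data = json.loads(path.read_text())
        orientations = {str(g): int(w) for g, w in data.items()}
    elif format == "gmt":
        up, dn = [], []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if name.endswith("_UP"):
                up.extend(genes)
            elif name.endswith("_DN"):
                dn.extend(genes)
            else:
                raise ValueError(f"GMT set {name!r} lacks the _UP/_DN suffix")
        conflict = set(up) & set(dn)
        if conflict:
            raise ValueError(f"genes present in both UP and DN sets: {sorted(conflict)[:5]}")
        orientations = {g: 1 for g in up}
        orientations.update({g: -1 for g in dn})
    else:
        raise ValueError(f"unknown signature format {format!r}")
    return SignedGeneSet(orientations=orientations, provenance={"path": str(path)})


def write_signature(sig: SignedGeneSet, path, format: str | None = None, *,
                    name: str = "IGF1_SIGNALLING") -> None:
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "json"
    if format == "json":
        path.write_text(json.dumps(sig.orientations, indent=1, sort_keys=True) + "\n")
    elif format == "gmt":
        lines = [
            "\t".join([f"{name}_UP", "up-regulated with stimulation"] + sig.up),
            "\t".join([f"{name}_DN", "down-regulated with stimulation"] + sig.down),
        ]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown signature format {format!r}")


_SUFFIX_DTYPES = {"num": float, "bool": bool, "cat": str}


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV with typed headers (``col:num`` etc.)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    out = {}
    for col in df.columns:
        name, _, suffix = col.rpartition(":")
        if not name or suffix not in _SUFFIX_DTYPES:
            out[col] = df[col]
            continue
        if suffix == "bool":
            vals = df[col].astype(str).str.lower()
            bad = ~vals.isin(["true", "false", "0", "1"])
            if bad.any():
                raise ValueError(f"column {col!r}: non-boolean values {df[col][bad].unique()[:5]}")
            out[name] = vals.isin(["true", "1"])
        else:
            out[name] = df[col].astype(_SUFFIX_DTYPES[suffix])
    res = pd.DataFrame(out, index=df.index)
    res.index.name = "sample"
    return res


def write_metadata(meta: pd.DataFrame, path) -> None:
    renamed = {}
    for col in meta.columns:
        if pd.api.types.is_bool_dtype(meta[col]):
            renamed[col] = f"{col}:bool"
        elif pd.api.types.is_numeric_dtype(meta[col]):
            renamed[col] = f"{col}:num"
        else:
            renamed[col] = f"{col}:cat"
    meta.rename(columns=renamed).to_csv(path, sep="\t")


def read_size_factors(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.iloc[:, 0].rename("size_factor")


def write_size_factors(s: pd.Series, path) -> None:
    s.rename("size_factor").to_csv(path, sep="\t", index_label="sample")
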
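"""Readers and writers for the pipeline's on-disk formats.

Counts travel as gene x sample TSV (first column gene ids, header row of
sample ids) or MatrixMarket triplets with companion row/column id files.
Annotations are TSV with a fixed column vocabulary, gene sets are standard
GMT, and fitted models / reports serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .containers import ExpressionMatrix, GeneSetCollection, Space


class GmtParseError(ValueError):
    """Malformed GMT content; message carries the offending line number."""


def read_counts_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, Space.raw_counts)


def write_counts_tsv(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(mtx_path, genes_path, samples_path) -> ExpressionMatrix:
    mat = mmread(mtx_path).toarray()
    genes = pd.read_csv(genes_path, header=None)[0].tolist()
    samples = pd.read_csv(samples_path, header=None)[0].tolist()
    df = pd.DataFrame(mat, index=genes, columns=samples)
    return ExpressionMatrix(df, Space.raw_counts)


def write_counts_mtx(m: ExpressionMatrix, mtx_path, genes_path, samples_path) -> None:
    mmwrite(str(mtx_path), csr_matrix(m.data.values))
    pd.Series(m.gene_ids).to_csv(genes_path, header=False, index=False)
    pd.Series(m.sample_ids).to_csv(samples_path, header=False, index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Raises
    ------
    GmtParseError
        On a line with fewer than three fields or a duplicate set name,
        naming the line number.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise GmtParseError(f"line {lineno}: duplicate gene set name {name!r}")
            if not members:
                raise GmtParseError(f"line {lineno}: gene set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            fields = [name, collection.description(name), *collection.members(name)]
            fh.write("\t".join(fields) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
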
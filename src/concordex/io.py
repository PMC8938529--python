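"""Readers and writers for the pipeline's plain-text artifacts.

Counts travel as TSV (genes in rows, sample ids in the header) or as
MatrixMarket triplets with sidecar row/column index files; sample metadata
and behavioral tables as CSV; gene sets as GMT; ground truth and reports as
JSON.  All writers accept an optional comment header (used to embed the
run-config hash) and all readers skip ``#`` comment lines, so round-trips
are exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import BehaviorTable, CountMatrix, DIRECTIONS, GroundTruth

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_metadata",
    "read_metadata",
    "write_behavior",
    "read_behavior",
    "read_gmt",
    "write_gmt",
    "write_ground_truth",
    "read_ground_truth",
]


def _comment_header(comment: str | None) -> str:
    if not comment:
        return ""
    return "".join(f"# {line}\n" for line in comment.splitlines())


def write_counts_tsv(counts: pd.DataFrame, path, comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_comment_header(comment))
        counts.to_csv(fh, sep="\t", index_label="gene")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "gene"
    return df


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """MatrixMarket triplet plus ``<prefix>.genes.txt``/``<prefix>.samples.txt``."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix) + ".mtx", sparse.coo_matrix(counts.to_numpy()))
    Path(str(prefix) + ".genes.txt").write_text("\n".join(counts.index) + "\n")
    Path(str(prefix) + ".samples.txt").write_text("\n".join(counts.columns) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = str(Path(prefix))
    m = spio.mmread(prefix + ".mtx").toarray()
    genes = Path(prefix + ".genes.txt").read_text().splitlines()
    samples = Path(prefix + ".samples.txt").read_text().splitlines()
    return pd.DataFrame(
        np.asarray(m, dtype=np.int64),
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )


def write_metadata(samples: pd.DataFrame, path, comment: str | None = None) -> None:
    with Path(path).open("w") as fh:
        fh.write(_comment_header(comment))
        samples.to_csv(fh, index_label="sample")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def write_count_matrix(cm: CountMatrix, prefix, comment: str | None = None) -> None:
    prefix = Path(prefix)
    write_counts_tsv(cm.counts, f"{prefix}.counts.tsv", comment)
    write_metadata(cm.samples, f"{prefix}.meta.csv", comment)


def read_count_matrix(prefix) -> CountMatrix:
    prefix = Path(prefix)
    return CountMatrix(
        counts=read_counts_tsv(f"{prefix}.counts.tsv"),
        samples=read_metadata(f"{prefix}.meta.csv"),
    )


def write_behavior(table: BehaviorTable, path, comment: str | None = None) -> None:
    meta = {"tests": table.tests, "directions": table.directions}
    header = (comment + "\n" if comment else "") + "meta: " + json.dumps(meta)
    with Path(path).open("w") as fh:
        fh.write(_comment_header(header))
        table.data.to_csv(fh, index_label="animal")


def read_behavior(path) -> BehaviorTable:
    meta = None
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("# meta: "):
                meta = json.loads(line[len("# meta: ") :])
            elif not line.startswith("#"):
                break
    data = pd.read_csv(path, comment="#", index_col=0)
    variables = [c for c in data.columns if c != "group"]
    if meta is None:
        meta = {
            "tests": {v: "unknown" for v in variables},
            "directions": {v: DIRECTIONS.get(v, 1) for v in variables},
        }
    return BehaviorTable(
        data=data,
        tests=dict(meta["tests"]),
        directions={k: int(v) for k, v in meta["directions"].items()},
    )


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """GMT gene sets: name -> (description, genes)."""
    sets: dict[str, tuple[str, set[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
        name, desc, *genes = parts
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = (desc, set(g for g in genes if g))
    return sets


def write_gmt(sets: Mapping[str, tuple[str, set]], path) -> None:
    lines = [
        "\t".join([name, desc] + sorted(genes)) for name, (desc, genes) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_table(df: pd.DataFrame, path, comment: str | None = None, index=True) -> None:
    """Generic TSV artifact writer with optional comment header."""
    with Path(path).open("w") as fh:
        fh.write(_comment_header(comment))
        df.to_csv(fh, sep="\t", index=index)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
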
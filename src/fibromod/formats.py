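"""Readers and writers for the standard text formats.

Dialects are pinned to the Broad conventions:

* GCT v1.2 — ``#1.2`` header line, a dims line (``n_genes\tn_samples``),
  then a header row ``Name  Description  <sample...>``;
* CLS — ``<n> <k> 1`` header (k = 2 enforced here), ``#``-prefixed class
  name line, then one label per sample (names or 0/1 indices);
* GMT — one gene set per line: name, description, then >= 1 genes;
* RNK — two tab-separated columns (gene, score), no header;

plus a lenient TSV alternative for expression matrices (gene column first,
one sample per remaining column). All round-trips are lossless up to the
documented normalization: identifiers uppercased, duplicates collapsed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GeneSet, RankedList
from .errors import ParseError
from .ranking import build_ranked_list

__all__ = [
    "read_gct", "write_gct", "read_cls", "write_cls",
    "read_gmt", "write_gmt", "read_rnk", "write_rnk",
    "read_expression_tsv", "write_expression_tsv",
    "read_gene_list", "read_expression",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- GCT / CLS

def read_gct(path: str | Path) -> ExpressionDataset:
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ParseError("GCT file too short", str(path))
    if lines[0].strip() != "#1.2":
        raise ParseError(f"expected '#1.2' version line, got {lines[0]!r}",
                         str(path), 1)
    dims = lines[1].split("\t")
    if len(dims) < 2:
        raise ParseError("dims line must be '<n_genes>\\t<n_samples>'",
                         str(path), 2)
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except ValueError as exc:
        raise ParseError(f"non-integer dims line: {lines[1]!r}", str(path), 2) from exc
    header = lines[2].split("\t")
    if len(header) != n_samples + 2:
        raise ParseError(
            f"header has {len(header) - 2} sample columns but dims line "
            f"declares {n_samples}", str(path), 3)
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_genes:
        raise ParseError(
            f"found {len(body)} data rows but dims line declares {n_genes}",
            str(path), 2)
    genes, rows = [], []
    for i, ln in enumerate(body):
        fields = ln.split("\t")
        if len(fields) != n_samples + 2:
            raise ParseError(
                f"row has {len(fields) - 2} values, expected {n_samples}",
                str(path), 4 + i)
        genes.append(fields[0])
        try:
            rows.append([float(v) for v in fields[2:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric expression value in row {fields[0]!r}",
                             str(path), 4 + i) from exc
    values = pd.DataFrame(np.array(rows), index=genes, columns=header[2:])
    return ExpressionDataset(values)


def write_gct(dataset: ExpressionDataset, path: str | Path) -> None:
    path = Path(path)
    df = dataset.values
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in zip(df.index, df.to_numpy()):
            vals = "\t".join(format(v, ".6g") for v in row)
            fh.write(f"{gene}\tna\t{vals}\n")


def read_cls(path: str | Path, n_samples: int | None = None) -> tuple[pd.Series, tuple[str, str]]:
    """Parse a two-class CLS file into (labels 0/1, (control, case) names)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ParseError("CLS file needs header, class-name line and label line",
                         str(path))
    head = lines[0].split()
    if len(head) < 3:
        raise ParseError(f"bad CLS header {lines[0]!r}", str(path), 1)
    n_declared, k = int(head[0]), int(head[1])
    if k != 2:
        raise ParseError(f"only two-class CLS supported, header declares {k}",
                         str(path), 1)
    if not lines[1].startswith("#"):
        raise ParseError("second CLS line must start with '#'", str(path), 2)
    names = lines[1][1:].split()
    if len(names) != 2:
        raise ParseError(f"expected 2 class names, got {names}", str(path), 2)
    tokens = lines[2].split()
    if len(tokens) != n_declared:
        raise ParseError(
            f"label line has {len(tokens)} entries but header declares "
            f"{n_declared}", str(path), 3)
    if n_samples is not None and n_declared != n_samples:
        raise ParseError(
            f"CLS declares {n_declared} samples but expression matrix has "
            f"{n_samples}", str(path), 1)
    if set(tokens) <= {"0", "1"}:
        labels = [int(t) for t in tokens]
    else:
        mapping = {names[0]: 0, names[1]: 1}
        try:
            labels = [mapping[t] for t in tokens]
        except KeyError as exc:
            raise ParseError(f"label {exc.args[0]!r} not among class names {names}",
                             str(path), 3) from exc
    return pd.Series(labels), (names[0], names[1])


def write_cls(dataset: ExpressionDataset, path: str | Path) -> None:
    if dataset.labels is None:
        raise ParseError("dataset has no phenotype labels to write")
    path = Path(path)
    labels = dataset.labels.to_numpy()
    with path.open("w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write(f"# {dataset.class_names[0]} {dataset.class_names[1]}\n")
        fh.write(" ".join(str(int(v)) for v in labels) + "\n")


# ------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> list[GeneSet]:
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} fields; need name, "
                    "description and >= 1 gene", str(path), lineno)
            name = fields[0].strip()
            if name in seen:
                raise ParseError(f"duplicate gene set name {name!r}",
                                 str(path), lineno)
            seen.add(name)
            sets.append(GeneSet.from_iterable(name, fields[2:], fields[1]))
    if not sets:
        raise ParseError("GMT file contains no gene sets", str(path))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in sets:
            if len(s) == 0:
                raise ParseError(f"cannot write empty gene set {s.name!r} to GMT")
            fh.write("\t".join([s.name, s.description or "na", *s.sorted_genes()]) + "\n")


# ------------------------------------------------------------------- RNK

def read_rnk(path: str | Path, direction: str = "descending") -> RankedList:
    """Read a two-column RNK file and (re)build the ranked list.

    Duplicate genes are collapsed by max |score| with a logged count; the
    list is re-sorted in the requested direction, so the file's own row
    order is not trusted.
    """
    path = Path(path)
    pairs: list[tuple[str, float]] = []
    with path.open() as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(f"RNK line needs 2 tab-separated fields, got "
                                 f"{len(fields)}", str(path), lineno)
            try:
                score = float(fields[1])
            except ValueError as exc:
                raise ParseError(f"non-numeric score {fields[1]!r}",
                                 str(path), lineno) from exc
            if not np.isfinite(score):
                raise ParseError(f"non-finite score for gene {fields[0]!r}",
                                 str(path), lineno)
            pairs.append((fields[0], score))
    if len(pairs) < 2:
        raise ParseError("RNK file needs >= 2 genes", str(path))
    return build_ranked_list(pairs, direction=direction)


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gene, score in zip(ranked.genes, ranked.scores):
            fh.write(f"{gene}\t{float(score)!r}\n")


# ------------------------------------------------------------------- TSV

def read_expression_tsv(path: str | Path) -> ExpressionDataset:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"could not parse TSV: {exc}", str(path)) from exc
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ParseError("TSV contains non-numeric expression columns", str(path))
    return ExpressionDataset(df)


def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    dataset.values.to_csv(Path(path), sep="\t", index_label="gene")


def read_expression(
    path: str | Path, cls_path: str | Path | None = None
) -> ExpressionDataset:
    """Dispatch on extension: .gct -> GCT, anything else -> TSV; attach CLS."""
    path = Path(path)
    ds = read_gct(path) if path.suffix.lower() == ".gct" else read_expression_tsv(path)
    if cls_path is not None:
        labels, names = read_cls(cls_path, n_samples=ds.n_samples)
        ds = ExpressionDataset(ds.values, labels=labels, class_names=names)
    return ds


def read_gene_list(path: str | Path, name: str = "GENES") -> GeneSet:
    """Plain text, one gene symbol per line; '#' lines ignored."""
    path = Path(path)
    genes = [
        ln.strip() for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not genes:
        raise ParseError("gene list file is empty", str(path))
    return GeneSet.from_iterable(name, genes)
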
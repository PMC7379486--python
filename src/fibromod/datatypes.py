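"""Core in-memory containers.

The pipeline passes four kinds of objects between stages: a genes x samples
expression matrix with an optional two-class phenotype (`ExpressionDataset`),
a totally ordered gene list with differential scores (`RankedList`), a named
gene set (`GeneSet`), and the result records of the enrichment and overlap
stages (`EnrichmentResult`, `OverlapResult`).

Gene identifiers are uppercased on ingestion everywhere, so that human and
mouse symbol casing (Postn vs POSTN) cannot silently split one gene into two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "ExpressionDataset",
    "RankedList",
    "GeneSet",
    "EnrichmentResult",
    "OverlapResult",
]


def normalize_gene(g: str) -> str:
    return str(g).strip().upper()


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with an optional two-class labeling.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes (identifiers uppercased, must be unique after
        uppercasing), columns are samples. Values are assumed to be on a
        log-like additive scale.
    labels : pandas.Series, optional
        Per-sample class labels, 0 = control/reference, 1 = case/treated.
        Index must match the sample columns.
    class_names : tuple of str
        Display names for classes (control, case).
    """

    values: pd.DataFrame
    labels: pd.Series | None = None
    class_names: tuple[str, str] = ("CONTROL", "CASE")

    def __post_init__(self) -> None:
        idx = pd.Index([normalize_gene(g) for g in self.values.index], name="gene")
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()[:5]
            raise ConfigError(
                f"duplicate gene identifiers after uppercasing: {dups} ..."
            )
        self.values = self.values.set_axis(idx, axis=0)
        if self.labels is not None:
            labels = pd.Series(self.labels)
            if len(labels) != self.values.shape[1]:
                raise ConfigError(
                    f"label count ({len(labels)}) != sample count "
                    f"({self.values.shape[1]})"
                )
            uniq = set(int(v) for v in labels)
            if not uniq <= {0, 1}:
                raise ConfigError(f"labels must be 0/1, got {sorted(uniq)}")
            self.labels = pd.Series(
                labels.to_numpy(dtype=int), index=self.values.columns
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def has_two_classes(self) -> bool:
        return self.labels is not None and set(self.labels) == {0, 1}

    def class_matrix(self, cls: int) -> np.ndarray:
        """Return the genes x samples submatrix of one class as an array."""
        if self.labels is None:
            raise ConfigError("dataset has no phenotype labels")
        mask = (self.labels == cls).to_numpy()
        return self.values.to_numpy()[:, mask]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique, uppercased gene identifiers."""

    name: str
    genes: frozenset[str]
    description: str = ""

    @classmethod
    def from_iterable(
        cls, name: str, genes: Iterable[str], description: str = ""
    ) -> "GeneSet":
        return cls(name, frozenset(normalize_gene(g) for g in genes), description)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalize_gene(gene) in self.genes

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass(frozen=True)
class RankedList:
    """Totally ordered list of unique genes with aligned differential scores.

    ``order`` records the direction actually applied ("descending" puts the
    most up-regulated genes first). Invariants: genes unique, len >= 2,
    scores sorted consistently with ``order``.
    """

    genes: tuple[str, ...]
    scores: np.ndarray
    order: str = "descending"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if len(self.genes) != len(scores):
            raise ConfigError("genes and scores must have equal length")
        if len(self.genes) < 2:
            raise ConfigError("a ranked list needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError("ranked list contains duplicate gene identifiers")
        if self.order not in ("descending", "ascending"):
            raise ConfigError(f"unknown order {self.order!r}")
        diffs = np.diff(scores)
        if self.order == "descending" and np.any(diffs > 0):
            raise ConfigError("scores not sorted in descending order")
        if self.order == "ascending" and np.any(diffs < 0):
            raise ConfigError("scores not sorted in ascending order")

    def __len__(self) -> int:
        return len(self.genes)

    def position(self, gene: str) -> int:
        """1-based rank of a gene."""
        return self.genes.index(normalize_gene(gene)) + 1


@dataclass
class EnrichmentResult:
    """Everything the enrichment stage computes for one (list, set) pair.

    ``running_sum[i-1]`` is the hit-minus-miss running sum after walking the
    first ``i`` list positions; it ends at 0. ``peak_index`` is the 1-based
    position of the signed extremum, with ties broken earliest for positive
    ES and latest for negative ES. ``es_null`` and the significance fields
    are filled by :func:`fibromod.enrichment.run_gsea`.
    """

    es: float
    running_sum: np.ndarray
    peak_index: int
    hit_positions: np.ndarray  # sorted, 1-based
    weight_p: int
    n_hits: int
    es_null: np.ndarray | None = None
    p_nominal: float | None = None
    nes: float | None = None
    fdr: float | None = None
    leading_edge: GeneSet | None = None
    n_perm: int | None = None
    seed: int | None = None
    set_name: str = ""


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of two gene sets within a finite universe."""

    k: int
    size_a: int
    size_b: int
    universe: int
    p_value: float
    dropped_a: int = 0
    dropped_b: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.size_a, self.size_b) <= self.universe):
            raise ConfigError(
                f"invalid overlap: k={self.k}, sizes=({self.size_a}, "
                f"{self.size_b}), universe={self.universe}"
            )
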
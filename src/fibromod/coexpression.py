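"""Marker-seeded coexpression module construction.

Given an expression compendium and a small set of marker genes, every other
gene is scored by its mean Fisher-z-transformed Pearson correlation to the
markers,

    zbar(g) = (1/|M|) * sum_{m in M} atanh(r(g, m)),

with correlations clipped to +/-0.999999 before atanh so a gene identical
to a marker still gets a finite score. Significance is empirical: the
gene's sample vector is permuted ``n_null`` times, zbar recomputed each
time, and the one-sided (positive-coexpression) p-value taken with the
add-one convention p = (1 + #{null >= observed}) / (1 + n_null), so p is
never exactly 0 and never below 1/(n_null + 1).

The module is then the markers plus every gene with p strictly below the
threshold (default 0.01). This is a local surrogate for
search-engine-style compendium queries (cross-validated coexpression
ranking over many curated datasets): it keeps the selection rule — rank by
coexpression with the markers, keep genes passing a p cutoff — while
defining the score and its null explicitly on the one compendium at hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GeneSet
from .errors import ConfigError

__all__ = [
    "CoexpressionTable",
    "coexpression_scores",
    "empirical_pvalues",
    "select_module",
    "build_module",
]

CLIP = 0.999999  # |r| bound before atanh; atanh(CLIP) ~ 7.254
MIN_SAMPLES = 10  # below this, sample correlations are too unstable to threshold
MIN_NULL = 99  # smallest n_null that can resolve p < 0.01


@dataclass
class CoexpressionTable:
    """Per-gene coexpression score and empirical p-value.

    ``table`` is indexed by gene (markers excluded) with columns ``zbar``
    and ``p_value`` (NaN until :func:`empirical_pvalues` fills it).
    """

    table: pd.DataFrame
    markers: GeneSet
    n_null: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.table.index) & self.markers.genes
        if overlap:
            raise ConfigError(f"markers present in the score table: {sorted(overlap)}")


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Row-standardize; constant rows become all-zero (correlation 0)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def _zbar_from_std(genes_std: np.ndarray, markers_std: np.ndarray) -> np.ndarray:
    """Mean Fisher-z correlation of each standardized gene row to the markers."""
    n = genes_std.shape[1]
    r = genes_std @ markers_std.T / n
    np.clip(r, -CLIP, CLIP, out=r)
    return np.arctanh(r).mean(axis=1)


def coexpression_scores(
    compendium: ExpressionDataset, markers: GeneSet
) -> CoexpressionTable:
    """Score every non-marker gene by mean Fisher-z correlation to the markers."""
    if compendium.n_samples < MIN_SAMPLES:
        raise ConfigError(
            f"compendium has {compendium.n_samples} samples; "
            f">= {MIN_SAMPLES} required for stable correlations"
        )
    missing = markers.genes - set(compendium.genes)
    if missing:
        raise ConfigError(f"marker(s) absent from compendium: {sorted(missing)}")
    marker_list = markers.sorted_genes()
    others = [g for g in compendium.genes if g not in markers.genes]
    if not others:
        raise ConfigError("compendium contains no non-marker genes")
    x = compendium.values.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(compendium.genes)}
    m_std = _standardize_rows(x[[gene_pos[m] for m in marker_list]])
    g_std = _standardize_rows(x[[gene_pos[g] for g in others]])
    zbar = _zbar_from_std(g_std, m_std)
    table = pd.DataFrame({"zbar": zbar, "p_value": np.nan}, index=pd.Index(others, name="gene"))
    return CoexpressionTable(table=table, markers=markers, n_null=0)


def empirical_pvalues(
    table: CoexpressionTable,
    compendium: ExpressionDataset,
    markers: GeneSet,
    n_null: int = 999,
    seed: int = 0,
) -> CoexpressionTable:
    """Fill one-sided permutation p-values for every scored gene.

    For gene g the null is generated by permuting g's sample vector
    ``n_null`` times (its own seeded sub-stream) and recomputing zbar
    against the unpermuted markers; only positive coexpression counts
    against the observed score.
    """
    if n_null < MIN_NULL:
        raise ConfigError(
            f"n_null must be >= {MIN_NULL} to resolve p < 0.01, got {n_null}"
        )
    marker_list = markers.sorted_genes()
    x = compendium.values.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(compendium.genes)}
    m_std = _standardize_rows(x[[gene_pos[m] for m in marker_list]])
    n = compendium.n_samples
    genes = list(table.table.index)
    children = np.random.SeedSequence(seed).spawn(len(genes))
    base = np.tile(np.arange(n), (n_null, 1))
    pvals = np.empty(len(genes))
    for i, g in enumerate(genes):
        rng = np.random.default_rng(children[i])
        perm = rng.permuted(base, axis=1)
        row_std = _standardize_rows(x[gene_pos[g]][None, :])[0]
        null_z = _zbar_from_std(row_std[perm], m_std)
        obs = table.table.at[g, "zbar"]
        pvals[i] = (1.0 + np.sum(null_z >= obs)) / (1.0 + n_null)
    out = table.table.copy()
    out["p_value"] = pvals
    return CoexpressionTable(table=out, markers=table.markers, n_null=n_null)


def select_module(
    table: CoexpressionTable,
    markers: GeneSet,
    p_threshold: float = 0.01,
    name: str = "MODULE",
) -> GeneSet:
    """Markers plus every gene with p strictly below the threshold.

    Strict inequality mirrors the "p < threshold" selection rule, so
    monotonicity holds: a looser threshold can only grow the module.
    Markers are always included regardless of their own scores.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ConfigError(f"p_threshold must lie in (0, 1], got {p_threshold}")
    p = table.table["p_value"]
    if p.isna().any():
        raise ConfigError("p-values not computed; run empirical_pvalues first")
    selected = set(p.index[p < p_threshold])
    return GeneSet.from_iterable(
        name,
        selected | set(markers.genes),
        f"markers + coexpressed genes at p < {p_threshold}",
    )


def build_module(
    compendium: ExpressionDataset,
    markers: GeneSet,
    p_threshold: float = 0.01,
    n_null: int = 999,
    seed: int = 0,
    name: str = "MODULE",
) -> tuple[GeneSet, CoexpressionTable]:
    """Convenience composition: score, compute p-values, select."""
    table = coexpression_scores(compendium, markers)
    table = empirical_pvalues(table, compendium, markers, n_null=n_null, seed=seed)
    return select_module(table, markers, p_threshold=p_threshold, name=name), table
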
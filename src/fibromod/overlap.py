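"""Hypergeometric overlap testing between core (leading-edge) gene sets.

The question is enrichment of shared membership: given two gene sets of
sizes a and b drawn from a universe of U genes, how surprising is an
overlap of at least k? The upper tail

    P(X >= k),  X ~ Hypergeometric(U, a, b)

is evaluated through scipy's log-space survival function. The default
universe is the module the core sets were extracted from — the smallest
defensible choice when both sets are leading-edge subsets of one module —
and is configurable.
"""

from __future__ import annotations

import logging

from scipy.stats import hypergeom

from .datatypes import GeneSet, OverlapResult
from .errors import ConfigError

__all__ = ["hypergeom_tail", "compare_core_genes"]

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, size_a: int, size_b: int, universe: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(universe, size_a, size_b)."""
    if universe < 1:
        raise ConfigError(f"universe must be >= 1, got {universe}")
    if not (0 <= size_a <= universe):
        raise ConfigError(f"size_a={size_a} outside [0, universe={universe}]")
    if not (0 <= size_b <= universe):
        raise ConfigError(f"size_b={size_b} outside [0, universe={universe}]")
    if not (0 <= k <= min(size_a, size_b)):
        raise ConfigError(
            f"k={k} outside [0, min(size_a, size_b)={min(size_a, size_b)}]"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy works on log probabilities internally
    return float(hypergeom.sf(k - 1, universe, size_a, size_b))


def compare_core_genes(
    core_a: GeneSet, core_b: GeneSet, universe_genes: GeneSet
) -> OverlapResult:
    """Hypergeometric overlap of two core sets within a gene universe.

    Members outside the universe are dropped with a warning and counted in
    the result, so a symbol-mapping loss (e.g. cross-species) is visible
    rather than silent.
    """
    if len(universe_genes) == 0:
        raise ConfigError("universe is empty")
    uni = universe_genes.genes
    a = core_a.genes & uni
    b = core_b.genes & uni
    dropped_a = len(core_a) - len(a)
    dropped_b = len(core_b) - len(b)
    if dropped_a or dropped_b:
        logger.warning(
            "dropped genes outside the universe: %d from %s, %d from %s",
            dropped_a, core_a.name, dropped_b, core_b.name,
        )
    k = len(a & b)
    p = hypergeom_tail(k, len(a), len(b), len(uni))
    return OverlapResult(
        k=k, size_a=len(a), size_b=len(b), universe=len(uni),
        p_value=p, dropped_a=dropped_a, dropped_b=dropped_b,
    )
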
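"""Simulation studies that characterize the pipeline on planted data.

Each function runs a self-contained experiment — generate data with known
ground truth, run the relevant stage(s), measure an operating
characteristic — and returns plain floats. They are used both by the test
suite and by the reproduction script, so the measured numbers always come
from the same code path.

Conventions: contrasts use a 50-gene module in a 2000-gene background with
20 case / 20 control samples and unit noise, the regime the screening
logic is specified for; module-recovery uses a 500-gene compendium of 150
samples with factor loading 1 and noise 0.5, giving a planted pairwise
correlation of 0.8. Seeds are derived from one root seed per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .coexpression import build_module
from .datatypes import GeneSet
from .enrichment import run_gsea
from .ranking import build_ranked_list, differential_scores
from .simulate import (
    SimulationConfig,
    planted_truth,
    simulate_compendium,
    simulate_contrast,
)

__all__ = [
    "CONTRAST_CONFIG",
    "RECOVERY_CONFIG",
    "null_calibration",
    "screen_detection_rate",
    "module_recovery",
    "leading_edge_recovery",
]

# screening regime: block shift of 1.5 noise-s.d. on a 50/2000-gene module
CONTRAST_CONFIG = SimulationConfig(
    n_genes=2000, n_samples=150, module_size=50, n_markers=3,
    beta=1.0, sigma=1.0, delta=1.5, n_case=20, n_control=20,
    effect_fraction=1.0, seed=0,
)

# module-recovery regime: planted correlation beta^2/(beta^2+sigma^2) = 0.8
RECOVERY_CONFIG = SimulationConfig(
    n_genes=500, n_samples=150, module_size=50, n_markers=3,
    beta=1.0, sigma=0.5, delta=0.0, n_case=20, n_control=20,
    effect_fraction=1.0, seed=0,
)


def _seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31, derived from one root seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _contrast_pvalue(
    config: SimulationConfig, direction: str, n_perm: int, seed: int,
    weight_p: int = 1,
) -> tuple[float, float]:
    """(es, p_nominal) of the planted module in one simulated contrast."""
    cfg = config.with_seed(seed)
    truth = planted_truth(cfg)
    data = simulate_contrast(cfg, truth, direction)
    ranked = build_ranked_list(
        differential_scores(data, "moderated_t"), "descending"
    )
    module = GeneSet.from_iterable("MODULE", truth.module_genes)
    res = run_gsea(ranked, module, weight_p=weight_p, n_perm=n_perm, seed=seed)
    return res.es, res.p_nominal


@dataclass
class CalibrationResult:
    p_values: np.ndarray
    rejection_rate: float  # fraction with p < alpha
    ks_distance: float  # KS distance from Uniform(0,1)
    ks_pvalue: float
    alpha: float


def null_calibration(
    n_reps: int = 500,
    alpha: float = 0.05,
    n_perm: int = 499,
    seed: int = 0,
    config: SimulationConfig = CONTRAST_CONFIG,
) -> CalibrationResult:
    """Type-I behaviour of the module p-value under delta = 0 contrasts.

    With no planted shift the module genes are exchangeable with the
    background, so the nominal p should be approximately Uniform(0, 1).
    """
    null_cfg = replace(config, delta=0.0)
    pvals = np.array([
        _contrast_pvalue(null_cfg, "up", n_perm, s)[1]
        for s in _seeds(seed, n_reps)
    ])
    ks = stats.kstest(pvals, "uniform")
    return CalibrationResult(
        p_values=pvals,
        rejection_rate=float(np.mean(pvals < alpha)),
        ks_distance=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        alpha=alpha,
    )


def screen_detection_rate(
    direction: str,
    n_seeds: int = 100,
    alpha: float = 0.05,
    n_perm: int = 499,
    seed: int = 0,
    config: SimulationConfig = CONTRAST_CONFIG,
) -> float:
    """Fraction of simulated contrasts the screen calls correctly.

    A disease-like ("up") contrast counts as detected when ES > 0 with
    p < alpha; a drug-like ("down") contrast when ES < 0 with p < alpha —
    the signature-reversal rule.
    """
    hits = 0
    for s in _seeds(seed, n_seeds):
        es, p = _contrast_pvalue(config, direction, n_perm, s)
        ok = es > 0 if direction == "up" else es < 0
        hits += int(ok and p < alpha)
    return hits / n_seeds


def module_recovery(
    n_seeds: int = 10,
    p_threshold: float = 0.01,
    n_null: int = 999,
    seed: int = 0,
    config: SimulationConfig = RECOVERY_CONFIG,
) -> tuple[float, float]:
    """Mean (precision, recall) of module selection against the planted truth."""
    precisions, recalls = [], []
    for s in _seeds(seed, n_seeds):
        cfg = config.with_seed(s)
        data, truth = simulate_compendium(cfg)
        markers = GeneSet.from_iterable("MARKERS", truth.marker_genes)
        module, _ = build_module(
            data, markers, p_threshold=p_threshold, n_null=n_null, seed=s
        )
        tp = len(module.genes & truth.module_genes)
        precisions.append(tp / len(module.genes))
        recalls.append(tp / len(truth.module_genes))
    return float(np.mean(precisions)), float(np.mean(recalls))


def leading_edge_recovery(
    n_seeds: int = 20,
    effect_fraction: float = 0.5,
    delta: float = 2.0,
    n_perm: int = 499,
    seed: int = 0,
    config: SimulationConfig = CONTRAST_CONFIG,
) -> float:
    """Mean fraction of shift-carrying genes recovered by the leading edge.

    Only ``effect_fraction`` of module genes carry the shift; the leading
    edge of the module's enrichment should concentrate on exactly those.
    """
    base = replace(config, effect_fraction=effect_fraction, delta=delta)
    fractions = []
    for s in _seeds(seed, n_seeds):
        cfg = base.with_seed(s)
        truth = planted_truth(cfg)
        data = simulate_contrast(cfg, truth, "up")
        ranked = build_ranked_list(
            differential_scores(data, "moderated_t"), "descending"
        )
        module = GeneSet.from_iterable("MODULE", truth.module_genes)
        res = run_gsea(ranked, module, weight_p=1, n_perm=n_perm, seed=s)
        le = res.leading_edge.genes
        fractions.append(len(le & truth.effected_genes) / len(truth.effected_genes))
    return float(np.mean(fractions))
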
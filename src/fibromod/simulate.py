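"""Synthetic expression data with planted, recoverable structure.

Three generators cover the stages the pipeline needs to exercise:

* a *compendium* in which a planted gene module shares a single latent
  factor with a handful of marker genes (a stand-in for tissue-level
  coexpression around fibroblast-activation markers such as POSTN, DDR2
  and PDGFRA);
* a *disease contrast*, a case/control dataset in which module genes are
  shifted up as a block in the case class;
* a *drug contrast*, the mirror image: module genes shifted down in the
  treated class, i.e. a signature-reversal profile.

Model: for sample ``s`` a latent factor ``f_s ~ N(0, 1)`` is drawn; a
module gene reads ``beta * f_s + N(0, sigma^2)`` and a background gene
``N(0, sigma^2)``. Two module genes therefore have population correlation
``beta^2 / (beta^2 + sigma^2)``, which gives a closed-form target for
tests. Contrasts drop the latent factor and add a signed mean shift
``delta`` to an ``effect_fraction`` of module genes in the case class.

All randomness flows from one integer seed through fixed, named
sub-streams, so every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GeneSet
from .errors import ConfigError

__all__ = ["SimulationConfig", "GroundTruth", "planted_truth",
           "simulate_compendium", "simulate_contrast"]

DEFAULT_MARKER_NAMES = ("POSTN", "DDR2", "PDGFRA")

# named sub-streams derived from the one user-facing seed
_STREAM_TRUTH = 0
_STREAM_COMPENDIUM = 1
_STREAM_CONTRAST_UP = 2
_STREAM_CONTRAST_DOWN = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-module generator.

    Attributes
    ----------
    n_genes : int
        Total genes (module + background).
    n_samples : int
        Samples in the compendium.
    module_size : int
        Planted module size, markers included.
    n_markers : int
        Number of marker genes (first slots of the module).
    beta : float
        Latent-factor loading of module genes; 0 disables coexpression.
    sigma : float
        Standard deviation of the iid Gaussian noise, > 0.
    delta : float
        Per-gene mean shift of effected module genes in the case class
        of a contrast (signed magnitude; direction chooses the sign).
    n_case, n_control : int
        Class sizes of a contrast.
    effect_fraction : float
        Fraction of module genes that carry the shift, in [0, 1].
    seed : int
        Root seed; all sub-streams are derived from it.
    """

    n_genes: int = 2000
    n_samples: int = 150
    module_size: int = 50
    n_markers: int = 3
    beta: float = 1.0
    sigma: float = 1.0
    delta: float = 1.5
    n_case: int = 20
    n_control: int = 20
    effect_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ConfigError("n_genes and n_samples must be positive")
        if not (1 <= self.n_markers <= self.module_size <= self.n_genes):
            raise ConfigError(
                f"need n_markers <= module_size <= n_genes, got "
                f"{self.n_markers} <= {self.module_size} <= {self.n_genes}"
            )
        if self.sigma <= 0:
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")
        if self.beta < 0:
            raise ConfigError(f"beta must be >= 0, got {self.beta}")
        if not (0.0 <= self.effect_fraction <= 1.0):
            raise ConfigError(
                f"effect_fraction must lie in [0, 1], got {self.effect_fraction}"
            )
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("n_case and n_control must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """The planted structure a recovery experiment is scored against."""

    module_genes: frozenset[str]
    marker_genes: frozenset[str]
    effected_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.marker_genes <= self.module_genes:
            raise ConfigError("marker_genes must be a subset of module_genes")
        if not self.effected_genes <= self.module_genes:
            raise ConfigError("effected_genes must be a subset of module_genes")

    def as_gene_sets(self) -> list[GeneSet]:
        return [
            GeneSet.from_iterable("MODULE", self.module_genes, "planted module"),
            GeneSet.from_iterable("MARKERS", self.marker_genes, "marker genes"),
            GeneSet.from_iterable("EFFECTED", self.effected_genes,
                                  "module genes carrying the shift"),
        ]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def gene_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Deterministic synthetic symbols: (module genes incl. markers, background).

    The first ``n_markers`` module slots carry marker names — POSTN, DDR2,
    PDGFRA when ``n_markers == 3``, MARKER1... otherwise. Remaining module
    genes are MOD0001..., background genes BG0001...
    """
    if config.n_markers == len(DEFAULT_MARKER_NAMES):
        markers = list(DEFAULT_MARKER_NAMES)
    else:
        markers = [f"MARKER{i + 1}" for i in range(config.n_markers)]
    module = markers + [
        f"MOD{i + 1:04d}" for i in range(config.module_size - config.n_markers)
    ]
    background = [
        f"BG{i + 1:04d}" for i in range(config.n_genes - config.module_size)
    ]
    return module, background


def planted_truth(config: SimulationConfig) -> GroundTruth:
    """Ground truth implied by a config: names plus the seeded effected subset.

    The effected subset is ``round(effect_fraction * module_size)`` module
    genes drawn without replacement from its own sub-stream, so compendium
    and contrast generation agree on it without sharing state.
    """
    module, _ = gene_names(config)
    markers = module[: config.n_markers]
    n_eff = int(round(config.effect_fraction * config.module_size))
    rng = _rng(config, _STREAM_TRUTH)
    effected = sorted(rng.choice(module, size=n_eff, replace=False)) if n_eff else []
    return GroundTruth(frozenset(module), frozenset(markers), frozenset(effected))


def simulate_compendium(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a single-latent-factor compendium with a planted coexpressed module.

    Returns the dataset (genes x samples, no phenotype) and the ground truth.
    Same config (including seed) gives byte-identical output.
    """
    module, background = gene_names(config)
    truth = planted_truth(config)
    rng = _rng(config, _STREAM_COMPENDIUM)
    n_mod, n_bg, n_s = len(module), len(background), config.n_samples
    f = rng.standard_normal(n_s)
    x = rng.normal(0.0, config.sigma, size=(config.n_genes, n_s))
    x[:n_mod] += config.beta * f[None, :]
    values = pd.DataFrame(
        x,
        index=module + background,
        columns=[f"S{i + 1:03d}" for i in range(n_s)],
    )
    return ExpressionDataset(values), truth


def simulate_contrast(
    config: SimulationConfig,
    truth: GroundTruth,
    direction: str,
) -> ExpressionDataset:
    """Draw a two-class case/control dataset with a block shift on the module.

    ``direction="up"`` adds ``+delta`` to effected module genes in the case
    class (disease-like); ``"down"`` adds ``-delta`` (drug-like signature
    reversal). All other genes have zero mean difference. Noise is iid
    ``N(0, sigma^2)``; the latent factor is not present in contrasts.
    """
    if direction not in ("up", "down"):
        raise ConfigError(f"direction must be 'up' or 'down', got {direction!r}")
    if not truth.module_genes:
        raise ConfigError("truth.module_genes is empty")
    module, background = gene_names(config)
    universe = set(module) | set(background)
    missing = truth.module_genes - universe
    if missing:
        raise ConfigError(
            f"truth genes not in the configured gene universe: {sorted(missing)[:5]}"
        )
    stream = _STREAM_CONTRAST_UP if direction == "up" else _STREAM_CONTRAST_DOWN
    rng = _rng(config, stream)
    genes = module + background
    n_s = config.n_control + config.n_case
    x = rng.normal(0.0, config.sigma, size=(config.n_genes, n_s))
    shift = config.delta if direction == "up" else -config.delta
    eff_idx = [i for i, g in enumerate(genes) if g in truth.effected_genes]
    x[np.asarray(eff_idx, dtype=int), config.n_control:] += shift
    labels = np.r_[np.zeros(config.n_control, int), np.ones(config.n_case, int)]
    values = pd.DataFrame(
        x, index=genes, columns=[f"S{i + 1:03d}" for i in range(n_s)]
    )
    class_names = ("CONTROL", "CASE" if direction == "up" else "TREATED")
    return ExpressionDataset(values, labels=pd.Series(labels), class_names=class_names)
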
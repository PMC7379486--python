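"""End-to-end screening pipeline.

Stages, in order: build the marker-seeded module from a compendium; rank
each contrast's genes by differential score; run preranked enrichment of
the module in each ranked list; extract leading edges; test pairwise
leading-edge overlap. One machine-readable JSON summary plus per-stage
TSV artifacts are written to the output directory.

The screening verdict per contrast encodes the signature-reversal rule: a
contrast is a "reversal_candidate" when the module is significantly
enriched at the bottom of its ranking (ES < 0, p < alpha) — the pattern
expected of a drug that switches the module off — and "disease_like" when
significantly enriched at the top.

A pipeline run without an explicit integer seed is refused: every
stochastic stage (coexpression null, enrichment null) must be reproducible.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .coexpression import build_module
from .datatypes import EnrichmentResult, GeneSet
from .enrichment import run_gsea
from .errors import ConfigError
from .formats import read_expression, read_gene_list, write_gmt
from .overlap import compare_core_genes
from .ranking import build_ranked_list, differential_scores
from .simulate import DEFAULT_MARKER_NAMES

__all__ = ["ContrastSpec", "PipelineConfig", "run_pipeline", "write_gsea_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    expression: str
    cls: str


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Defaults: selection threshold p < 0.01, markers POSTN/DDR2/PDGFRA,
    moderated-t ranking in descending order (most up-regulated first),
    weighted enrichment (p = 1), 1000 enrichment permutations, 999
    coexpression permutations, alpha 0.05.
    """

    compendium: str
    contrasts: list[ContrastSpec]
    seed: int
    out_dir: str
    markers: str | None = None  # path to a one-symbol-per-line file
    p_threshold: float = 0.01
    ranking_method: str = "moderated_t"
    direction: str = "descending"
    weight_p: int = 1
    n_perm: int = 1000
    n_null: int = 999
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"pipeline config {path} is not a mapping")
        if "seed" not in raw or raw["seed"] is None:
            raise ConfigError(
                "pipeline config must set an explicit integer 'seed'; "
                "refusing to run unseeded"
            )
        try:
            raw["seed"] = int(raw["seed"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"seed must be an integer, got {raw['seed']!r}") from exc
        contrasts = [
            ContrastSpec(c["name"], c["expression"], c["cls"])
            for c in raw.get("contrasts", [])
        ]
        if not contrasts:
            raise ConfigError("pipeline config lists no contrasts")
        names = [c.name for c in contrasts]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate contrast names: {names}")
        known = {f.name for f in cls.__dataclass_fields__.values()}
        extra = set(raw) - known
        if extra:
            raise ConfigError(f"unknown config key(s): {sorted(extra)}")
        raw["contrasts"] = contrasts
        return cls(**raw)


def write_gsea_report(
    results: list[EnrichmentResult], path: str | Path
) -> None:
    """One TSV row per analyzed gene set (ES, NES, p, FDR, leading edge)."""
    with Path(path).open("w") as fh:
        fh.write(
            "set\tn_hits\tes\tnes\tp_nominal\tfdr\tpeak_index\tleading_edge\n"
        )
        for r in results:
            le = ";".join(r.leading_edge.sorted_genes()) if r.leading_edge else ""
            fh.write(
                f"{r.set_name}\t{r.n_hits}\t{r.es:.6g}\t{r.nes:.6g}\t"
                f"{r.p_nominal:.6g}\t{r.fdr:.6g}\t{r.peak_index}\t{le}\n"
            )


def write_running_sum(result: EnrichmentResult, path: str | Path) -> None:
    """Running-sum trace TSV (position, running_sum, is_hit) for plotting."""
    hits = set(int(p) for p in result.hit_positions)
    with Path(path).open("w") as fh:
        fh.write("position\trunning_sum\tis_hit\n")
        for i, v in enumerate(result.running_sum, start=1):
            fh.write(f"{i}\t{v:.6g}\t{int(i in hits)}\n")


def _verdict(es: float, p: float, alpha: float) -> str:
    if p < alpha and es < 0:
        return "reversal_candidate"
    if p < alpha and es > 0:
        return "disease_like"
    return "not_significant"


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full screen; returns (and writes) the summary mapping."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline config: %s", config)

    if config.markers is not None:
        markers = read_gene_list(config.markers, name="MARKERS")
    else:
        markers = GeneSet.from_iterable("MARKERS", DEFAULT_MARKER_NAMES)
    compendium = read_expression(config.compendium)
    module, table = build_module(
        compendium,
        markers,
        p_threshold=config.p_threshold,
        n_null=config.n_null,
        seed=config.seed,
        name="MODULE",
    )
    logger.info("module: %d genes (markers %s)", len(module),
                ",".join(markers.sorted_genes()))
    write_gmt([module, markers], out / "module.gmt")
    table.table.sort_index().to_csv(out / "coexpression.tsv", sep="\t",
                                    float_format="%.6g")

    contrast_summaries: dict[str, Any] = {}
    results: list[EnrichmentResult] = []
    edges: dict[str, GeneSet] = {}
    for spec in config.contrasts:
        data = read_expression(spec.expression, cls_path=spec.cls)
        scores = differential_scores(data, config.ranking_method)
        ranked = build_ranked_list(scores, config.direction)
        res = run_gsea(
            ranked, module, weight_p=config.weight_p,
            n_perm=config.n_perm, seed=config.seed,
        )
        res.set_name = f"MODULE@{spec.name}"
        results.append(res)
        edges[spec.name] = res.leading_edge
        write_running_sum(res, out / f"running_sum_{spec.name}.tsv")
        contrast_summaries[spec.name] = {
            "n_hits": res.n_hits,
            "es": round(res.es, 10),
            "nes": round(res.nes, 10),
            "p_nominal": round(res.p_nominal, 10),
            "fdr": round(res.fdr, 10),
            "peak_index": res.peak_index,
            "leading_edge_size": len(res.leading_edge),
            "verdict": _verdict(res.es, res.p_nominal, config.alpha),
        }
        logger.info("contrast %s: ES=%.3f p=%.4g verdict=%s", spec.name,
                    res.es, res.p_nominal,
                    contrast_summaries[spec.name]["verdict"])
    write_gsea_report(results, out / "gsea_report.tsv")

    overlaps: dict[str, Any] = {}
    for a, b in itertools.combinations(sorted(edges), 2):
        if len(edges[a]) == 0 or len(edges[b]) == 0:
            logger.warning("skipping overlap %s vs %s: empty leading edge", a, b)
            continue
        ov = compare_core_genes(edges[a], edges[b], module)
        overlaps[f"{a}|{b}"] = {
            "k": ov.k, "size_a": ov.size_a, "size_b": ov.size_b,
            "universe": ov.universe, "p_value": round(ov.p_value, 10),
        }

    summary = {
        "seed": config.seed,
        "module_size": len(module),
        "markers": markers.sorted_genes(),
        "p_threshold": config.p_threshold,
        "ranking": {"method": config.ranking_method,
                    "direction": config.direction},
        "weight_p": config.weight_p,
        "n_perm": config.n_perm,
        "n_null": config.n_null,
        "alpha": config.alpha,
        "contrasts": contrast_summaries,
        "overlaps": overlaps,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
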
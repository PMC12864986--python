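"""End-to-end orchestration: annotation -> clustering -> Epromoter calls.

A :class:`RunConfig` names the three required inputs (refGene annotation,
induced-gene TSV, one or more TF peak BEDs) plus optional TADs, and
``run()`` produces the pipeline's two main outputs per clustering method —
the per-gene cluster/binding table and the Epromoter-regulated cluster
table — alongside a dataset summary JSON, the bubble-grid occupancy table
and a run log.  Outputs are deterministic: fixed column order, sorted rows,
floats printed with 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation import Gene, collapse_genes, load_annotation
from .calling import (
    ClusterCall,
    DatasetSummary,
    bubble_grid,
    classify_clusters,
    merge_nonredundant,
    summarize_dataset,
)
from .clustering import GeneCluster, cluster_by_distance, cluster_by_tad
from .intervals import GenomicInterval, read_bed
from .proximity import read_induced_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "PipelineError", "run", "aggregate"]

DEFAULT_CRITERIA = {"distance": "fewer_than_n", "tad": "exactly_one"}


class PipelineError(RuntimeError):
    """A fatal pipeline input/configuration problem."""


@dataclass
class RunConfig:
    dataset_id: str
    annotation: str
    induced: str
    peaks: dict[str, str]                  # TF label -> BED path
    genome_build: str = "custom"
    tads: str | None = None
    methods: tuple[str, ...] = ("distance",)
    max_gap: int = 100_000
    promoter_flank: int = 1000
    criteria: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CRITERIA))
    coding_only: bool = True
    smallest_tad_only: bool = False
    seed: int = 0
    outdir: str = "epromoters_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        criteria = dict(DEFAULT_CRITERIA)
        criteria.update(data.get("criteria", {}))
        data["criteria"] = criteria
        return cls(**data)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["methods"] = list(self.methods)
        out.pop("outdir")  # implied by the output location
        return out


@dataclass
class RunResult:
    config: RunConfig
    genes: list[Gene]
    induced_genes: list[Gene]
    missing_symbols: list[str]
    clusters: dict[str, list[GeneCluster]]
    calls: dict[str, list[ClusterCall]]
    summaries: dict[str, DatasetSummary]
    paths: dict[str, Path]


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def _match_induced(
    induced_df: pd.DataFrame, genes: Sequence[Gene]
) -> tuple[list[Gene], dict[str, float], list[str]]:
    by_symbol = {g.symbol: g for g in genes}
    matched: list[Gene] = []
    fold: dict[str, float] = {}
    missing: list[str] = []
    for symbol, fc in zip(induced_df["symbol"], induced_df["fold_change"]):
        gene = by_symbol.get(symbol)
        if gene is None:
            missing.append(symbol)
        elif symbol not in fold:  # first occurrence wins
            matched.append(gene)
            fold[symbol] = float(fc)
    return matched, fold, missing


def _clusters_frame(
    clusters: Sequence[GeneCluster], fold: Mapping[str, float]
) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "method": c.method,
            "chrom": c.chrom,
            "span_start": c.span.start,
            "span_end": c.span.end,
            "n_genes": c.n_genes,
            "gene_symbols": ";".join(c.symbols),
            "fold_changes": ";".join(_fmt(fold[s]) for s in c.symbols),
            "tad_id": c.tad_id or "",
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "method", "chrom", "span_start", "span_end",
            "n_genes", "gene_symbols", "fold_changes", "tad_id",
        ],
    )


def _binding_frame(
    calls: Sequence[ClusterCall], fold: Mapping[str, float], tf_labels: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for call in calls:
        for g in call.cluster.genes:
            row = {
                "cluster_id": call.cluster.cluster_id,
                "chrom": g.chrom,
                "gene_symbol": g.symbol,
                "canonical_tss": g.canonical_tss,
                "strand": g.strand,
                "fold_change": _fmt(fold[g.symbol]),
                "n_genes": call.n_genes,
                "n_bound": call.n_bound,
                "category": call.category,
                "bound_any": int(call.bound_flags[g.symbol]),
            }
            for tf in tf_labels:
                row[f"bound_{tf}"] = int(call.per_tf_flags[tf][g.symbol])
            rows.append(row)
    cols = [
        "cluster_id", "chrom", "gene_symbol", "canonical_tss", "strand",
        "fold_change", "n_genes", "n_bound", "category", "bound_any",
    ] + [f"bound_{tf}" for tf in tf_labels]
    return pd.DataFrame(rows, columns=cols)


def _epromoter_frame(
    calls: Sequence[ClusterCall], fold: Mapping[str, float]
) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": c.cluster.cluster_id,
            "chrom": c.cluster.chrom,
            "span_start": c.cluster.span.start,
            "span_end": c.cluster.span.end,
            "n_genes": c.n_genes,
            "n_bound": c.n_bound,
            "gene_symbols": ";".join(c.cluster.symbols),
            "fold_changes": ";".join(_fmt(fold[s]) for s in c.cluster.symbols),
            "epromoter_genes": ";".join(c.epromoter_genes),
            "coinduced_genes": ";".join(c.coinduced_genes),
        }
        for c in calls
        if c.category == "epromoter_regulated"
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "chrom", "span_start", "span_end", "n_genes", "n_bound",
            "gene_symbols", "fold_changes", "epromoter_genes", "coinduced_genes",
        ],
    )


def run(config: RunConfig) -> RunResult:
    """Execute annotation loading, clustering, classification and reporting."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("epromoters")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    paths: dict[str, Path] = {"log": outdir / "run.log"}
    try:
        logger.info("epromoters %s; dataset %s; seed %d",
                    __version__, config.dataset_id, config.seed)
        for name in ("annotation", "induced"):
            p = Path(getattr(config, name))
            if not p.is_file():
                raise PipelineError(f"{name} file not readable: {p}")
        transcripts = load_annotation(config.annotation, coding_only=config.coding_only)
        genes = collapse_genes(transcripts)
        use_prefix = genes[0].chrom.startswith("chr")
        logger.info("annotation: %d transcripts -> %d genes", len(transcripts), len(genes))

        induced_df = read_induced_table(config.induced)
        induced, fold, missing = _match_induced(induced_df, genes)
        if missing:
            logger.warning(
                "%d induced symbols absent from the annotation (e.g. %s)",
                len(missing), ", ".join(missing[:5]),
            )
        if not induced:
            raise PipelineError("no induced symbols match the annotation")
        logger.info("induced genes matched: %d / %d", len(induced), len(induced_df))

        peaks_by_tf: dict[str, list[GenomicInterval]] = {}
        for tf, path in config.peaks.items():
            if not Path(path).is_file():
                raise PipelineError(f"peak file for {tf} not readable: {path}")
            peaks_by_tf[tf] = read_bed(path, chrom_prefix=use_prefix)
            logger.info("peaks[%s]: %d intervals", tf, len(peaks_by_tf[tf]))

        tads = None
        if config.tads:
            tads = read_bed(config.tads, chrom_prefix=use_prefix)
            logger.info("tads: %d intervals", len(tads))

        tf_labels = sorted(peaks_by_tf)
        clusters: dict[str, list[GeneCluster]] = {}
        calls: dict[str, list[ClusterCall]] = {}
        summaries: dict[str, DatasetSummary] = {}
        for method in config.methods:
            if method == "distance":
                cl = cluster_by_distance(induced, config.max_gap, config.dataset_id)
            elif method == "tad":
                if tads is None:
                    raise PipelineError("TAD clustering requested without a TAD file")
                cl = cluster_by_tad(
                    induced, tads, config.dataset_id,
                    smallest_only=config.smallest_tad_only,
                )
            else:
                raise PipelineError(f"unknown clustering method {method!r}")
            criterion = config.criteria.get(method, DEFAULT_CRITERIA[method])
            cc = classify_clusters(cl, peaks_by_tf, criterion, config.promoter_flank)
            summary = summarize_dataset(cc, config.dataset_id, len(induced))
            clusters[method], calls[method], summaries[method] = cl, cc, summary
            logger.info(
                "%s method: %d clusters (%d genes), %d epromoter_regulated",
                method, summary.n_clusters, summary.n_genes_in_clusters,
                summary.n_epromoter_clusters,
            )

            _clusters_frame(cl, fold).to_csv(
                outdir / f"clusters.{method}.tsv", sep="\t", index=False
            )
            _binding_frame(cc, fold, tf_labels).to_csv(
                outdir / f"clusters_with_binding.{method}.tsv", sep="\t", index=False
            )
            _epromoter_frame(cc, fold).to_csv(
                outdir / f"epromoter_clusters.{method}.tsv", sep="\t", index=False
            )
            bubble_grid(cc).to_csv(
                outdir / f"bubble_grid.{method}.tsv", sep="\t", index=False
            )
            with open(outdir / f"summary.{method}.json", "w") as fh:
                json.dump(dataclasses.asdict(summary), fh, indent=2, sort_keys=True)
                fh.write("\n")
            paths.update(
                {
                    f"clusters.{method}": outdir / f"clusters.{method}.tsv",
                    f"clusters_with_binding.{method}": outdir
                    / f"clusters_with_binding.{method}.tsv",
                    f"epromoter_clusters.{method}": outdir
                    / f"epromoter_clusters.{method}.tsv",
                    f"bubble_grid.{method}": outdir / f"bubble_grid.{method}.tsv",
                    f"summary.{method}": outdir / f"summary.{method}.json",
                }
            )

        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh, sort_keys=True)
        paths["config"] = outdir / "config.yaml"
        missing_path = outdir / "missing_symbols.txt"
        missing_path.write_text("".join(f"{s}\n" for s in missing))
        paths["missing_symbols"] = missing_path
        return RunResult(
            config=config,
            genes=genes,
            induced_genes=induced,
            missing_symbols=missing,
            clusters=clusters,
            calls=calls,
            summaries=summaries,
            paths=paths,
        )
    finally:
        root.removeHandler(handler)
        handler.close()


def aggregate(
    summaries: Sequence[DatasetSummary],
    calls_by_dataset: Mapping[str, tuple[str, Sequence[ClusterCall]]] | None = None,
) -> dict:
    """Cross-dataset report: frequency table, pooled shares, non-redundant total.

    ``calls_by_dataset`` maps dataset_id -> (genome_build, calls); when
    given, the pooled bubble grid, pooled one-/fewer-bound shares and the
    non-redundant Epromoter-cluster count are included.
    """
    if not summaries:
        raise ValueError("at least one dataset summary is required")
    table = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    report: dict = {
        "n_datasets": len(summaries),
        "per_dataset": table,
        "mean_epromoter_clusters_per_dataset": float(
            table["n_epromoter_clusters"].mean()
        ),
        "median_freq_epromoter": float(table["freq_epromoter"].median()),
        "median_freq_all_bound": float(table["freq_all_bound"].median()),
    }
    if calls_by_dataset is not None:
        pooled = [c for _, calls in calls_by_dataset.values() for c in calls]
        with_binding = [c for c in pooled if c.n_bound >= 1]
        report["pooled_bubble_grid"] = bubble_grid(pooled)
        report["one_bound_share"] = (
            sum(1 for c in with_binding if c.n_bound == 1) / len(with_binding)
            if with_binding
            else float("nan")
        )
        report["fewer_bound_share"] = (
            sum(1 for c in with_binding if c.n_bound < c.n_genes) / len(with_binding)
            if with_binding
            else float("nan")
        )
        by_build: dict[str, list[ClusterCall]] = {}
        for build, calls in calls_by_dataset.values():
            by_build.setdefault(build, []).extend(calls)
        total, merged = merge_nonredundant(by_build)
        report["nonredundant_epromoter_clusters"] = total
        report["nonredundant_table"] = merged
    return report
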
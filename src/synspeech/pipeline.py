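"""End-to-end two-group analysis: load → MDD → indices → networks → statistics.

`run_pipeline` reproduces the full analysis shape on any pair of corpora:
per-transcript text MDD and syntactic-index vectors, a two-group MDD
comparison, pooled word-type dependency networks with summary statistics,
node-metric comparisons over the vertices shared by both networks, the
cross-difference of the two networks, and a stepwise regression of MDD on
the screened index set within each group.  Every number in the report is
recomputed from the inputs and configuration; reruns with the same config
(and seed, for synthetic corpora) are identical apart from no state at all
being cached.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .dependency_distance import MddConvention, mdd_text
from .dependency_network import (
    DependencyNetwork,
    build_network,
    network_difference,
    node_metrics,
    pajek_summary,
    weighted_degrees,
)
from .grammar_indices import INDEX_NAMES, compute_all_indices
from .group_inference import (
    GroupComparison,
    RegressionModel,
    ScreeningReport,
    compare_groups,
    correlation_screen,
    stepwise_regression,
    vif_screen,
)
from .treebank_io import Treebank, TreebankError, read_conllu_dir, write_pajek_net

logger = logging.getLogger("synspeech")

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    group_a_path: str = ""
    group_b_path: str = ""
    group_a_label: str = "A"
    group_b_label: str = "B"
    mdd_convention: str = "stated_rule"
    index_set: tuple[str, ...] = INDEX_NAMES
    alpha: float = 0.05
    r_min: float = 0.100
    vif_threshold: float = 5.0
    p_enter: float = 0.05
    p_remove: float = 0.10
    network_top_k: int = 200
    seed: int = 0
    output_dir: str = ""

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


@dataclass
class AnalysisReport:
    config: PipelineConfig
    mdd_table: pd.DataFrame           # transcript, group, mdd, n_tokens, n_links
    index_table: pd.DataFrame         # transcript, group, 20 indices + ttr
    mdd_comparison: GroupComparison
    metric_comparisons: dict[str, GroupComparison]
    network_summaries: dict[str, dict[str, float]]
    top_weighted: dict[str, list[tuple[str, float]]]
    screening: dict[str, ScreeningReport]
    regressions: dict[str, RegressionModel]
    networks: dict[str, DependencyNetwork] = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "package": "synspeech",
                "version": __version__,
                "config": dataclasses.asdict(self.config),
            },
            "mdd": {
                "comparison": self.mdd_comparison.as_dict(),
            },
            "node_metric_comparisons": {
                name: cmp.as_dict() for name, cmp in self.metric_comparisons.items()
            },
            "network_summaries": self.network_summaries,
            "top_weighted": self.top_weighted,
            "screening": {
                label: {
                    "retained": rep.retained,
                    "dropped_correlation": rep.dropped_correlation,
                    "dropped_vif": rep.dropped_vif,
                }
                for label, rep in self.screening.items()
            },
            "regressions": {
                label: model.as_dict() for label, model in self.regressions.items()
            },
        }


def _load_group(path: str, label: str) -> list[Treebank]:
    transcripts = read_conllu_dir(path, group_label=label)
    if not transcripts:
        raise TreebankError(f"group {label}: empty corpus at {path}")
    return transcripts


def _per_transcript_tables(
    transcripts: list[Treebank], label: str, convention: MddConvention,
    index_set: tuple[str, ...],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    mdd_rows = []
    index_rows = []
    for tb in transcripts:
        try:
            result = mdd_text(tb, convention)
            mdd_value = result.text_value
            n_links = result.n_links_used
        except TreebankError:
            logger.warning("transcript %s: MDD undefined, skipped", tb.source_path)
            mdd_value, n_links = np.nan, 0
        mdd_rows.append({
            "transcript": tb.source_path, "group": label,
            "mdd": mdd_value, "n_tokens": tb.n_tokens, "n_links": n_links,
        })
        vector = compute_all_indices(tb)
        row: dict[str, object] = {"transcript": tb.source_path, "group": label}
        for name in index_set:
            value = vector.values.get(name)
            row[name] = np.nan if value is None else value
        row["ttr"] = vector.ttr
        index_rows.append(row)
    return pd.DataFrame(mdd_rows), pd.DataFrame(index_rows)


def _pooled(transcripts: list[Treebank], label: str) -> Treebank:
    sentences = [s for tb in transcripts for s in tb.sentences]
    return Treebank(sentences, group_label=label, source_path=f"pooled:{label}")


def _fit_group_model(
    index_frame: pd.DataFrame, mdd: pd.Series, config: PipelineConfig,
) -> tuple[ScreeningReport, RegressionModel]:
    features = index_frame[list(config.index_set)].astype(float)
    mask = mdd.notna()
    features, y = features[mask], mdd[mask]
    corr = correlation_screen(features, y, alpha=config.alpha, r_min=config.r_min)
    retained = corr.retained
    report = ScreeningReport(retained=retained,
                             dropped_correlation=corr.dropped_correlation)
    if len(retained) >= 2:
        vif_rep = vif_screen(features[retained].dropna(),
                             threshold=config.vif_threshold)
        report.dropped_vif = vif_rep.dropped_vif
        report.retained = vif_rep.retained
    if not report.retained:
        empty = RegressionModel(selected=[],
                                coefficients=pd.DataFrame(
                                    columns=["B", "SE", "beta", "VIF"]),
                                r_squared=0.0, adjusted_r_squared=0.0)
        return report, empty
    model = stepwise_regression(features[report.retained], y,
                                p_enter=config.p_enter, p_remove=config.p_remove)
    return report, model


def run_pipeline(
    config: PipelineConfig,
    transcripts_a: list[Treebank] | None = None,
    transcripts_b: list[Treebank] | None = None,
) -> AnalysisReport:
    """Execute the full analysis for two groups of transcripts.

    Corpora are read from ``config.group_a_path`` / ``group_b_path``
    (directories of ``.conllu`` files, one per transcript) unless
    transcript lists are passed directly (as the synthetic generator
    produces them).  Outputs are written under ``config.output_dir`` when
    it is set: report.json, mdd.csv, indices.csv, node_metrics.csv and one
    ``.net`` file per group plus the cross-difference network.
    """
    label_a, label_b = config.group_a_label, config.group_b_label
    if transcripts_a is None:
        transcripts_a = _load_group(config.group_a_path, label_a)
    if transcripts_b is None:
        transcripts_b = _load_group(config.group_b_path, label_b)
    for label, group in ((label_a, transcripts_a), (label_b, transcripts_b)):
        if not group:
            raise TreebankError(f"group {label}: empty corpus")

    convention = MddConvention.preset(config.mdd_convention)
    logger.info("stage mdd+indices: %d vs %d transcripts",
                len(transcripts_a), len(transcripts_b))
    mdd_a, idx_a = _per_transcript_tables(transcripts_a, label_a, convention,
                                          config.index_set)
    mdd_b, idx_b = _per_transcript_tables(transcripts_b, label_b, convention,
                                          config.index_set)
    mdd_table = pd.concat([mdd_a, mdd_b], ignore_index=True)
    index_table = pd.concat([idx_a, idx_b], ignore_index=True)

    mdd_comparison = compare_groups(mdd_a["mdd"].dropna(), mdd_b["mdd"].dropna())

    logger.info("stage networks")
    net_a = build_network(_pooled(transcripts_a, label_a))
    net_b = build_network(_pooled(transcripts_b, label_b))
    summaries = {label_a: pajek_summary(net_a), label_b: pajek_summary(net_b)}
    for label, net in ((label_a, net_a), (label_b, net_b)):
        summaries[label].update({"n": net.n, "m": net.m,
                                 "total_weight": net.total_weight})
    metrics_a = node_metrics(net_a)
    metrics_b = node_metrics(net_b)
    shared = [v for v in net_a.vertices if v in set(net_b.vertices)]
    metric_comparisons = {}
    for name in ("betweenness", "closeness", "clustering"):
        col_a = [getattr(metrics_a, name)[v] for v in shared]
        col_b = [getattr(metrics_b, name)[v] for v in shared]
        metric_comparisons[name] = compare_groups(col_a, col_b)
    top_weighted = {
        label_a: weighted_degrees(net_a, config.network_top_k),
        label_b: weighted_degrees(net_b, config.network_top_k),
    }
    diff = network_difference(net_a, net_b, top_k=config.network_top_k)

    logger.info("stage regression")
    screening: dict[str, ScreeningReport] = {}
    regressions: dict[str, RegressionModel] = {}
    for label, idx_frame, mdd_frame in (
        (label_a, idx_a, mdd_a), (label_b, idx_b, mdd_b),
    ):
        screening[label], regressions[label] = _fit_group_model(
            idx_frame, mdd_frame["mdd"], config
        )

    report = AnalysisReport(
        config=config,
        mdd_table=mdd_table,
        index_table=index_table,
        mdd_comparison=mdd_comparison,
        metric_comparisons=metric_comparisons,
        network_summaries=summaries,
        top_weighted=top_weighted,
        screening=screening,
        regressions=regressions,
        networks={label_a: net_a, label_b: net_b, "difference": diff},
    )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        mdd_table.to_csv(out / "mdd.csv", index=False)
        index_table.to_csv(out / "indices.csv", index=False)
        metric_rows = []
        for label, metrics, net in ((label_a, metrics_a, net_a),
                                    (label_b, metrics_b, net_b)):
            for v in net.vertices:
                metric_rows.append({
                    "group": label, "vertex": v,
                    "degree": metrics.degree[v],
                    "weighted_degree": metrics.weighted_degree[v],
                    "betweenness": metrics.betweenness[v],
                    "closeness": metrics.closeness[v],
                    "clustering": metrics.clustering[v],
                })
        pd.DataFrame(metric_rows).to_csv(out / "node_metrics.csv", index=False)
        write_pajek_net(net_a, out / f"network_{label_a}.net")
        write_pajek_net(net_b, out / f"network_{label_b}.net")
        write_pajek_net(diff, out / "network_difference.net")
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, default=str), encoding="utf-8"
        )
    return report
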
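"""End-to-end pipeline: ingest -> histories -> sampling -> pair statistics
-> calibration -> filters -> networks -> summaries -> organ aggregation.

Configured by :class:`PipelineConfig` (JSON or YAML on disk); every run
writes a machine-readable manifest recording stage counts, the cutoff used
and the seed, so runs are reproducible and auditable.  All stochastic
stages (equal sampling) draw from streams derived from the single config
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import comorbidity as cm
from . import ingest as ing
from . import network_analysis as na
from .icd9 import chapter_name, chapter_of

__all__ = [
    "PipelineConfig",
    "export_edgelist",
    "export_graphml",
    "export_organ_graphml",
    "read_graphml",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; round-trips through JSON/YAML."""

    input_path: str
    out_dir: str
    columns: dict[str, str] = field(default_factory=dict)
    sep: str | None = None
    sci_cutoff: float | str = 0.04  # a number, or "calibrate"
    alpha: float = 0.01
    organ_threshold: float = 10.0
    equal_sample: bool = True
    equal_sample_target: int | str = "min-group"
    per_group_calibration: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.organ_threshold < 0:
            raise ValueError("organ_threshold must be >= 0")
        if isinstance(self.sci_cutoff, str):
            if self.sci_cutoff != "calibrate":
                raise ValueError("sci_cutoff must be a number or 'calibrate'")
        elif self.sci_cutoff < 0:
            raise ValueError("sci_cutoff must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = open(path).read()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_graphml(network: cm.MultimorbidityNetwork, path) -> None:
    """GraphML with node attributes (code, chapter_id, degree,
    weighted_degree) and the sci edge attribute; losslessly re-importable."""
    g = nx.Graph()
    g.graph.update(
        group_label=network.group_label,
        cutoff_used=float(network.cutoff_used),
        filter_mean_used=float(network.filter_mean_used),
    )
    wdeg = na.weighted_degree_centrality(network)
    for v in network.graph.nodes:
        g.add_node(
            v,
            code=str(v),
            chapter_id=int(chapter_of(v)),
            degree=int(network.graph.degree(v)),
            weighted_degree=float(wdeg[v]),
        )
    for u, v, d in network.graph.edges(data=True):
        g.add_edge(u, v, sci=float(d["sci"]), c_ij=int(d.get("c_ij", 0)))
    nx.write_graphml(g, path)


def read_graphml(path) -> cm.MultimorbidityNetwork:
    raw = nx.read_graphml(path)
    g = nx.Graph()
    g.add_nodes_from(str(v) for v in raw.nodes)
    for u, v, d in raw.edges(data=True):
        g.add_edge(str(u), str(v), sci=float(d["sci"]), c_ij=int(d.get("c_ij", 0)), phi=float("nan"))
    return cm.MultimorbidityNetwork(
        group_label=str(raw.graph.get("group_label", "")),
        graph=g,
        cutoff_used=float(raw.graph.get("cutoff_used", 0.0)),
        filter_mean_used=float(raw.graph.get("filter_mean_used", float("nan"))),
    )


def export_edgelist(network: cm.MultimorbidityNetwork, path, sep: str = "\t") -> None:
    rows = [
        (u, v, f"{d['sci']:.12g}")
        for u, v, d in sorted(network.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["code_i", "code_j", "sci"]).to_csv(path, sep=sep, index=False)


def export_organ_graphml(organ: na.OrganNetwork, path) -> None:
    g = nx.Graph()
    g.graph.update(group_label=organ.group_label, highlight_threshold=float(organ.highlight_threshold))
    for v in organ.graph.nodes:
        g.add_node(
            v,
            name=chapter_name(int(v)),
            self_weight=float(organ.self_weights.get(int(v), 0.0)),
        )
    for u, v, d in organ.graph.edges(data=True):
        g.add_edge(u, v, weight=float(d["weight"]), highlighted=bool(d["highlighted"]))
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"].append({"stage": name, **counts})
    log.info("stage %-18s %s", name, counts)


def group_pair_stats(histories: list[ing.PatientHistory], alpha: float) -> tuple[pd.DataFrame, set[str]]:
    """Pair table for one group plus its diagnosed-code set."""
    X, codes = cm.lifetime_matrix(histories)
    return cm.pair_stats_from_matrix(X, codes, alpha=alpha), set(codes)


def build_group_networks(
    histories: dict[str, list[ing.PatientHistory]],
    sci_cutoff: float | str = 0.04,
    alpha: float = 0.01,
    per_group_calibration: bool = False,
) -> tuple[dict[str, cm.MultimorbidityNetwork], dict[str, pd.DataFrame], float | dict[str, float]]:
    """Histories -> per-group filtered pair tables and thresholded networks.

    When ``sci_cutoff`` is "calibrate", the cutoff is calibrated on the
    pooled (entire) dataset and applied to every group, unless
    ``per_group_calibration`` asks for one cutoff per group.
    """
    tables = {g: group_pair_stats(h, alpha) for g, h in histories.items()}
    if sci_cutoff == "calibrate":
        if per_group_calibration:
            cutoffs = {g: cm.calibrate_cutoff(t, alpha) for g, (t, _) in tables.items()}
        else:
            pooled = [h for hs in histories.values() for h in hs]
            pooled_pairs, _ = group_pair_stats(pooled, alpha)
            c = cm.calibrate_cutoff(pooled_pairs, alpha)
            cutoffs = {g: c for g in histories}
    else:
        cutoffs = {g: float(sci_cutoff) for g in histories}
    networks, filtered = {}, {}
    for g in sorted(histories):
        pairs, diagnosed = tables[g]
        kept, mean_used = cm.filter_below_average(pairs)
        filtered[g] = kept
        networks[g] = cm.build_network(
            kept, cutoffs[g], group_label=g, diagnosed_codes=diagnosed, filter_mean=mean_used
        )
    cutoff_out = cutoffs if per_group_calibration and sci_cutoff == "calibrate" else next(iter(cutoffs.values()))
    return networks, filtered, cutoff_out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed, "stages": []}

    records = ing.read_visits(config.input_path, columns=config.columns or None, sep=config.sep)
    _stage(manifest, "read", rows=len(records), patients=records["patient_id"].nunique())

    report = ing.DropReport()
    cleaned, report = ing.clean_visits(records, report)
    _stage(manifest, "clean", rows=len(cleaned), patients=cleaned["patient_id"].nunique())
    resolved, report = ing.resolve_race(cleaned, report)
    _stage(manifest, "resolve_race", rows=len(resolved), patients=resolved["patient_id"].nunique())
    manifest["drop_report"] = report.to_dict()
    (out / "drop_report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))

    histories = ing.build_histories(resolved)
    _stage(manifest, "histories", **{g: len(h) for g, h in sorted(histories.items())})
    ing.summarize(histories, resolved).to_csv(out / "cohort_summary.csv")

    if config.equal_sample and len(histories) > 1:
        histories = ing.equal_sample(histories, config.equal_sample_target, seed=config.seed)
        _stage(manifest, "equal_sample", **{g: len(h) for g, h in sorted(histories.items())})
    ing.write_histories(histories, out / "histories.csv")

    networks, filtered, cutoff_used = build_group_networks(
        histories, config.sci_cutoff, config.alpha, config.per_group_calibration
    )
    manifest["cutoff_used"] = cutoff_used
    manifest["filter_mean_used"] = {g: networks[g].filter_mean_used for g in sorted(networks)}
    for g in sorted(networks):
        filtered[g].to_csv(out / f"pairs_{g}.csv", index=False, float_format="%.12g")
        export_graphml(networks[g], out / f"network_{g}.graphml")
        export_edgelist(networks[g], out / f"network_{g}.edgelist.tsv")
    _stage(manifest, "networks", **{g: networks[g].n_edges for g in sorted(networks)})

    summaries = [na.summarize_network(networks[g]) for g in sorted(networks)]
    summary_df = pd.DataFrame([asdict(s) for s in summaries]).set_index("group_label")
    summary_df.to_csv(out / "network_summary.csv", float_format="%.6g")
    manifest["network_summary"] = json.loads(summary_df.to_json(orient="index"))
    if len(networks) >= 2:
        f_deg, p_deg = na.compare_group_degrees(networks.values(), weighted=False)
        f_w, p_w = na.compare_group_degrees(networks.values(), weighted=True)
        chi2_k, p_k = na.density_proportion_test_k([networks[g] for g in sorted(networks)])
        manifest["comparisons"] = {
            "anova_degree": {"F": f_deg, "p": p_deg},
            "anova_weighted_degree": {"F": f_w, "p": p_w},
            "edge_density_chi2": {"chi2": chi2_k, "p": p_k},
        }

    organs = [na.aggregate_to_organs(networks[g], threshold=config.organ_threshold) for g in sorted(networks)]
    for on in organs:
        export_organ_graphml(on, out / f"organ_{on.group_label}.graphml")
    presence = na.presence_table(organs)
    presence.to_csv(out / "organ_presence.csv")
    manifest["organ_highlighted_counts"] = {on.group_label: len(on.highlighted_pairs()) for on in organs}
    _stage(manifest, "organs", **manifest["organ_highlighted_counts"])

    text = json.dumps(manifest, indent=2, sort_keys=True)
    (out / "manifest.json").write_text(text)
    return manifest
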
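"""Config-driven end-to-end analysis: hierarchy, networks, diagnostics.

``run_pipeline`` reproduces the shape of a full camera-trap social-system
analysis from one config: the adult dominance hierarchy over the whole
study (restrict -> dominance matrix -> David's scores -> ranks), and one
association network per named period (co-occurrence -> association weights
-> eigenvector centrality -> fast-greedy clustering), with an optional
collapse map merging ids into a single node (e.g. a pup cohort). Outputs
are deterministic CSV/GraphML/JSON artifacts.
"""

from __future__ import annotations

import datetime as dt
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import dominance as dom
from . import socialnet as sn
from .obs_model import ObservationLog, read_event_log, restrict_log
from .reliability import ConfusionTable, acf, cohens_kappa, detection_series

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "PipelineError",
    "run_pipeline",
    "export_network",
    "read_graphml_network",
    "read_edgelist_network",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs, loadable from a flat YAML file."""

    roster_path: str
    events_path: str
    periods: dict[str, tuple[dt.date, dt.date]]
    out_dir: str
    dominance_life_stages: tuple[str, ...] = ("adult",)
    collapse_map: dict[str, str] = field(default_factory=dict)
    weight_kind: str = "count"
    scent_mark_fanout: bool = True
    acf_bin_days: float = 1.0
    acf_max_lag: int | None = None
    modularity_threshold: float = sn.STRONG_STRUCTURE_THRESHOLD
    confusion_table_path: str | None = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not self.periods:
            raise ValueError("at least one period must be defined")
        for name, (start, end) in self.periods.items():
            if start > end:
                raise ValueError(f"period {name!r} has start > end")
        overlap = set(self.collapse_map) & set(self.collapse_map.values())
        if overlap:
            raise ValueError(
                f"collapse targets must be distinct from collapsed ids: {sorted(overlap)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        periods = {
            name: (dt.date.fromisoformat(str(v["start"])), dt.date.fromisoformat(str(v["end"])))
            for name, v in raw["periods"].items()
        }
        kwargs = {k: v for k, v in raw.items() if k != "periods"}
        if "collapse_map" in kwargs and kwargs["collapse_map"] is None:
            kwargs["collapse_map"] = {}
        if "dominance_life_stages" in kwargs:
            kwargs["dominance_life_stages"] = tuple(kwargs["dominance_life_stages"])
        return cls(periods=periods, **kwargs)


@dataclass
class PeriodReport:
    name: str
    n_observations: int
    network: sn.SocialNetwork
    centrality: sn.CentralityScores
    partition: sn.Partition
    dendrogram: sn.MergeDendrogram


@dataclass
class ReportBundle:
    hierarchy: dom.DavidsScoreTable
    dominance_matrix: dom.DominanceMatrix
    periods: dict[str, PeriodReport]
    acf_result: object
    kappa_result: object | None
    paths: dict[str, str]
    skipped_events: int


def export_network(
    network: sn.SocialNetwork,
    partition: sn.Partition | None,
    scores: sn.CentralityScores | None,
    path: str | Path,
    format: str = "graphml",
    node_attrs: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write a network as GraphML or an edge-list CSV.

    GraphML nodes carry sex/life_stage (when given via ``node_attrs``),
    centrality and community attributes; edges carry their weight with
    full float precision so a re-import reproduces the matrix exactly.
    """
    path = Path(path)
    if format == "edgelist":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("source,target,weight\n")
            for a, b, w in network.edges():
                fh.write(f"{a},{b},{w!r}\n")
        return
    if format != "graphml":
        raise ValueError(f"unknown export format {format!r}")

    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    keys = [
        ("d_weight", "edge", "weight", "double"),
        ("d_centrality", "node", "centrality", "double"),
        ("d_community", "node", "community", "string"),
        ("d_sex", "node", "sex", "string"),
        ("d_stage", "node", "life_stage", "string"),
    ]
    for kid, domain, name, ktype in keys:
        ET.SubElement(
            root, "key", id=kid, **{"for": domain, "attr.name": name, "attr.type": ktype}
        )
    graph = ET.SubElement(root, "graph", id="G", edgedefault="undirected")
    score_map = scores.as_dict() if scores else {}
    for code in network.ids:
        node = ET.SubElement(graph, "node", id=code)
        if code in score_map:
            ET.SubElement(node, "data", key="d_centrality").text = repr(score_map[code])
        if partition is not None:
            ET.SubElement(node, "data", key="d_community").text = str(
                partition.labels[code]
            )
        for attr_key, attr_name in (("d_sex", "sex"), ("d_stage", "life_stage")):
            if node_attrs and code in node_attrs and attr_name in node_attrs[code]:
                ET.SubElement(node, "data", key=attr_key).text = node_attrs[code][
                    attr_name
                ]
    for i, (a, b, w) in enumerate(network.edges()):
        edge = ET.SubElement(graph, "edge", id=f"e{i}", source=a, target=b)
        ET.SubElement(edge, "data", key="d_weight").text = repr(w)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_graphml_network(path: str | Path, weight_kind: str = "count") -> sn.SocialNetwork:
    """Re-import a GraphML file written by :func:`export_network`."""
    ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
    root = ET.parse(path).getroot()
    graph = root.find("g:graph", ns)
    if graph is None:
        raise ValueError(f"{path}: no <graph> element")
    ids = [node.attrib["id"] for node in graph.findall("g:node", ns)]
    idx = {code: i for i, code in enumerate(ids)}
    weights = np.zeros((len(ids), len(ids)))
    for edge in graph.findall("g:edge", ns):
        a, b = idx[edge.attrib["source"]], idx[edge.attrib["target"]]
        w = 0.0
        for data in edge.findall("g:data", ns):
            if data.attrib.get("key") == "d_weight":
                w = float(data.text or 0.0)
        weights[a, b] = weights[b, a] = w
    return sn.SocialNetwork(ids=tuple(ids), weights=weights, weight_kind=weight_kind)


def read_edgelist_network(path: str | Path, weight_kind: str = "count") -> sn.SocialNetwork:
    """Re-import an edge-list CSV written by :func:`export_network`."""
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    ids = sorted({r["source"] for r in rows} | {r["target"] for r in rows})
    idx = {code: i for i, code in enumerate(ids)}
    weights = np.zeros((len(ids), len(ids)))
    for r in rows:
        a, b = idx[r["source"]], idx[r["target"]]
        weights[a, b] = weights[b, a] = float(r["weight"])
    return sn.SocialNetwork(ids=tuple(ids), weights=weights, weight_kind=weight_kind)


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Run the full analysis described by ``config`` and write all outputs.

    On any stage failure, files already written by this run are removed
    and a :class:`PipelineError` naming the stage is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def emit(line: str) -> None:
        log_lines.append(line)

    def track(path: Path) -> Path:
        written.append(path)
        return path

    try:
        return _run(config, out_dir, emit, track, log_lines)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("unknown", str(exc)) from exc


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return None

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def _run(config, out_dir, emit, track, log_lines) -> ReportBundle:
    emit(f"config: {config}")
    paths: dict[str, str] = {}

    with _stage("read"):
        log = read_event_log(config.roster_path, config.events_path)
        emit(f"read {len(log)} events, roster of {len(log.roster)}")

    full_start = min(start for start, _ in config.periods.values())
    full_end = max(end for _, end in config.periods.values())

    with _stage("dominance"):
        adult_log = restrict_log(
            log, full_start, full_end, life_stages=config.dominance_life_stages
        )
        matrix = dom.build_dominance_matrix(
            adult_log, scent_mark_fanout=config.scent_mark_fanout
        )
        table = dom.rank_hierarchy(dom.davids_scores(matrix))
        emit(
            f"dominance: {int(matrix.wins.sum())} wins over {len(matrix.ids)} adults, "
            f"{matrix.skipped_unidentified} events skipped (unidentified)"
        )
        hier_path = track(out_dir / "hierarchy.csv")
        frame = table.to_frame()
        stage_of = {ind.id: ind for ind in log.roster}
        frame.insert(1, "life_stage", [stage_of[c].life_stage for c in frame["id"]])
        frame.insert(2, "sex", [stage_of[c].sex for c in frame["id"]])
        frame.to_csv(hier_path, index=False)
        paths["hierarchy"] = str(hier_path)
        mat_path = track(out_dir / "dominance_matrix.csv")
        matrix.write_csv(mat_path)
        paths["dominance_matrix"] = str(mat_path)

    with _stage("acf"):
        series = detection_series(
            log, dt.timedelta(days=config.acf_bin_days)
        )
        acf_res = acf(series, config.acf_max_lag)
        emit(
            f"acf: {acf_res.n} bins, lags 1..{acf_res.lags[-1]}, "
            f"max |r| = {acf_res.max_abs():.4f}"
        )

    kappa_res = None
    if config.confusion_table_path:
        with _stage("kappa"):
            table_conf = ConfusionTable.read_csv(config.confusion_table_path)
            kappa_res = cohens_kappa(table_conf)
            emit(f"kappa: {kappa_res.kappa:.4f} (n={table_conf.n})")

    periods: dict[str, PeriodReport] = {}
    node_attrs = {
        ind.id: {"sex": ind.sex, "life_stage": ind.life_stage} for ind in log.roster
    }
    for target in set(config.collapse_map.values()):
        node_attrs[target] = {"sex": "unknown", "life_stage": "juvenile"}

    for name, (start, end) in sorted(config.periods.items()):
        with _stage(f"network:{name}"):
            period_log = restrict_log(log, start, end)
            raw_nodes = sorted(
                {
                    code
                    for events in period_log.recordings().values()
                    for ev in events
                    for code in ev.identified_participants()
                }
            )
            nodes = sorted(
                {config.collapse_map.get(code, code) for code in raw_nodes}
            )
            summary = sn.cooccurrence_counts(
                period_log, nodes, collapse_map=config.collapse_map
            )
            network = sn.association_matrix(summary, config.weight_kind)
            scores = sn.eigenvector_centrality(network)
            partition, dendrogram = sn.fast_greedy_partition(network)
            n_obs = int((summary.x.sum() - np.diagonal(summary.x).sum()) // 2)
            emit(
                f"period {name}: {len(period_log)} events, {len(nodes)} nodes, "
                f"{n_obs} dyadic associations, Q = {partition.q:.6f}, "
                f"strong_structure = {partition.strong_structure}"
            )

            cent_path = track(out_dir / f"{name}_centrality.csv")
            with open(cent_path, "w", encoding="utf-8", newline="") as fh:
                fh.write("individual,eigenvector_centrality\n")
                for code, score in zip(scores.ids, scores.scores):
                    fh.write(f"{code},{score!r}\n")
                fh.write(f"Modularity,{partition.q!r}\n")
            part_path = track(out_dir / f"{name}_partition.csv")
            with open(part_path, "w", encoding="utf-8", newline="") as fh:
                fh.write("individual,community\n")
                for code in network.ids:
                    fh.write(f"{code},{partition.labels[code]}\n")
            gml_path = track(out_dir / f"{name}.graphml")
            export_network(
                network, partition, scores, gml_path, "graphml", node_attrs
            )
            edge_path = track(out_dir / f"{name}_edges.csv")
            export_network(network, partition, scores, edge_path, "edgelist")
            paths[f"{name}_centrality"] = str(cent_path)
            paths[f"{name}_partition"] = str(part_path)
            paths[f"{name}_graphml"] = str(gml_path)
            paths[f"{name}_edges"] = str(edge_path)
            periods[name] = PeriodReport(
                name=name,
                n_observations=n_obs,
                network=network,
                centrality=scores,
                partition=partition,
                dendrogram=dendrogram,
            )

    with _stage("summary"):
        summary_path = track(out_dir / "summary.json")
        payload = {
            "hierarchy": {
                code: {
                    "norm_ds": float(table.norm_ds[i]),
                    "rank": int(table.rank[i]),
                }
                for i, code in enumerate(table.ids)
            },
            "skipped_events_unidentified": matrix.skipped_unidentified,
            "acf": {"n": acf_res.n, "r": list(acf_res.r)},
            "kappa": (
                {"p_o": kappa_res.p_o, "p_e": kappa_res.p_e, "kappa": kappa_res.kappa}
                if kappa_res
                else None
            ),
            "periods": {
                name: {
                    "n_observations": rep.n_observations,
                    "modularity": rep.partition.q,
                    "strong_structure": rep.partition.strong_structure,
                    "n_communities": rep.partition.n_communities(),
                    "centrality": rep.centrality.as_dict(),
                }
                for name, rep in periods.items()
            },
        }
        summary_path.write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        paths["summary"] = str(summary_path)
        log_path = track(out_dir / "run.log")
        log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        paths["log"] = str(log_path)

    return ReportBundle(
        hierarchy=table,
        dominance_matrix=matrix,
        periods=periods,
        acf_result=acf_res,
        kappa_result=kappa_res,
        paths=paths,
        skipped_events=matrix.skipped_unidentified,
    )
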
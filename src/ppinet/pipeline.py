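"""End-to-end orchestration: network -> metrics -> fits -> key nodes ->
complexes -> crosstalk -> regulatory network -> motifs -> enrichment.

A single :class:`PipelineConfig` drives every stage; stages whose inputs are
absent from the config are skipped, and stages downstream of a failed stage
are skipped with a logged reason.  All outputs are deterministic given the
same config and inputs (logs carry timestamps; data files do not) and every
summary carries a hash of the config it was produced from.

A *replay* mode accepts printed summary tables — a top-10 hub/bottleneck
ranking, or a bottleneck-hub x subnetwork strength matrix — so the key-node
intersection and crosstalk stages can be exercised on published values when
the underlying network is not redistributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import crosstalk as _crosstalk
from . import enrichment as _enrichment
from . import keynodes as _keynodes
from . import netio, regnet, topology
from .keynodes import KeyNodeReport
from .mcode import MCODEParams, predict_complexes

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run",
    "replay_keynodes",
    "replay_crosstalk",
]

#: short column names used in the metrics TSV
_METRIC_HEADERS = {
    "degree": "k",
    "clustering": "C",
    "neighborhood_connectivity": "CN",
    "betweenness": "CB",
    "closeness": "Cc",
    "eigenvector": "CE",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    network: str | None = None
    network_format: str | None = None
    normalize_ids: bool = False
    top_n: int = 10
    mcode: MCODEParams = field(default_factory=MCODEParams)
    n_complexes: int = 5
    signed_layers: dict = field(default_factory=dict)   # layer -> path
    mirna_sources: dict = field(default_factory=dict)   # source name -> path
    min_support: int | None = None
    gene_sets: str | None = None
    ora_alpha: float = 0.05
    outdir: str = "ppinet_out"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "mcode" in raw and isinstance(raw["mcode"], dict):
            raw["mcode"] = MCODEParams(**raw["mcode"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if self.top_n < 1:
            raise PipelineError("config: top_n must be >= 1")
        if self.n_complexes < 1:
            raise PipelineError("config: n_complexes must be >= 1")
        if not 0 < self.ora_alpha <= 1:
            raise PipelineError("config: ora_alpha must be in (0, 1]")
        for stage, paths in (
            ("network", [self.network] if self.network else []),
            ("regnet", self.signed_layers.values()),
            ("consensus", self.mirna_sources.values()),
            ("enrichment", [self.gene_sets] if self.gene_sets else []),
        ):
            for p in paths:
                if not Path(p).exists():
                    raise PipelineError(f"stage {stage}: input file not found: {p}")
        unknown = set(self.signed_layers) - set(netio.LAYERS)
        if unknown:
            raise PipelineError(f"stage regnet: unknown layers {sorted(unknown)}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logging.getLogger("ppinet").addHandler(handler)

    summary: dict = {"config_hash": config.config_hash(), "skipped": {}}
    complexes = []
    try:
        net = None
        if config.network:
            net = netio.read_network(
                config.network, format=config.network_format, normalize=config.normalize_ids
            )
            summary["network"] = {
                "nodes": net.number_of_nodes(),
                "edges": net.number_of_edges(),
            }
            metrics = topology.compute_node_metrics(net)
            out = metrics.rename(columns=_METRIC_HEADERS)
            _write_tsv(out.sort_index(), outdir / "node_metrics.tsv")

            fits = {}
            dist = topology.degree_distribution(net)
            for name, agg in [("degree_distribution", dist)] + [
                (m, topology.aggregate_by_degree(metrics, m))
                for m in topology.METRIC_FIELDS
                if m != "degree"
            ]:
                try:
                    fits[name] = topology.fit_power_law(agg).to_dict()
                except topology.InsufficientDataError as exc:
                    fits[name] = {"error": str(exc)}
            _write_json(fits, outdir / "power_law_fits.json")
            summary["fits"] = fits

            report = _keynodes.key_node_report(metrics, n=config.top_n)
            _write_json(report.to_dict(), outdir / "key_nodes.json")
            summary["key_nodes"] = report.to_dict()

            complexes = predict_complexes(net, config.mcode)[: config.n_complexes]
            rows = [
                {
                    "rank": c.rank,
                    "score": round(c.score, 4),
                    "n_nodes": len(c.members),
                    "n_edges": c.edge_count,
                    "members": ",".join(sorted(map(str, c.members))),
                }
                for c in complexes
            ]
            _write_tsv(pd.DataFrame(rows), outdir / "complexes.tsv", index=False)
            for c in complexes:
                netio.write_network(
                    net.subgraph(c.members), outdir / f"complex_SN{c.rank}_edges.tsv"
                )
            summary["complexes"] = rows

            bnhs = list(report.bottleneck_hubs)
            if bnhs and complexes:
                matrix = _crosstalk.crosstalk_matrix(net, bnhs, complexes)
                _write_tsv(matrix, outdir / "crosstalk.tsv")
                summary["crosstalk"] = {
                    "totals": matrix["Total"].to_dict(),
                    "key_mediator": _crosstalk.key_mediator(matrix),
                }
            else:
                summary["skipped"]["crosstalk"] = "no bottleneck-hubs or no complexes"
        else:
            for stage in ("metrics", "fits", "keynodes", "complexes", "crosstalk"):
                summary["skipped"][stage] = "no network input configured"
    except netio.NetworkFormatError as exc:
        raise PipelineError(f"stage network: {exc}") from exc

    if config.mirna_sources:
        sources = {
            name: {
                (e.source, e.target)
                for e in netio.read_signed_edges(
                    path, "mirna_gene", normalize=config.normalize_ids, default_sign=-1
                )
            }
            for name, path in sorted(config.mirna_sources.items())
        }
        consensus = regnet.consensus_targets(sources, config.min_support)
        frame = pd.DataFrame(sorted(consensus), columns=["mirna", "gene"])
        _write_tsv(frame, outdir / "consensus_targets.tsv", index=False)
        summary["consensus_targets"] = len(consensus)
    else:
        summary["skipped"]["consensus"] = "no miRNA target sources configured"

    if config.signed_layers:
        edge_lists = [
            netio.read_signed_edges(
                path,
                layer,
                normalize=config.normalize_ids,
                default_sign=-1 if layer == "mirna_gene" else None,
            )
            for layer, path in sorted(config.signed_layers.items())
        ]
        rnet = regnet.assemble(*edge_lists)
        motifs = regnet.enumerate_ffls(rnet)
        loops = regnet.enumerate_feedback_loops(rnet)
        _write_tsv(
            pd.DataFrame([dataclasses.asdict(m) for m in motifs]),
            outdir / "ffl_motifs.tsv",
            index=False,
        )
        _write_tsv(
            pd.DataFrame(
                [dataclasses.asdict(l) | {"loop_sign": l.loop_sign} for l in loops]
            ),
            outdir / "feedback_loops.tsv",
            index=False,
        )
        _write_json(rnet.summary(), outdir / "regnet_summary.json")
        summary["regnet"] = rnet.summary() | {
            "ffl_motifs": len(motifs),
            "coherent": sum(m.coherence == "coherent" for m in motifs),
            "incoherent": sum(m.coherence == "incoherent" for m in motifs),
            "feedback_loops": len(loops),
        }
    else:
        summary["skipped"]["regnet"] = "no signed regulatory layers configured"

    if config.gene_sets:
        if complexes:
            sets = netio.read_gene_sets(config.gene_sets, normalize=config.normalize_ids)
            background = set().union(*(s.members for s in sets))
            enrich_counts = {}
            for c in complexes:
                query = set(map(str, c.members)) & background
                if not query:
                    summary["skipped"][f"enrichment_SN{c.rank}"] = "no annotated members"
                    continue
                result = _enrichment.ora(query, sets, background, alpha=config.ora_alpha)
                _write_tsv(result, outdir / f"enrichment_SN{c.rank}.tsv", index=False)
                enrich_counts[f"SN-{c.rank}"] = int(result["significant"].sum())
            summary["enrichment_significant_terms"] = enrich_counts
        else:
            summary["skipped"]["enrichment"] = "no complexes to enrich"

    _write_json(summary, outdir / "summary.json")
    return summary


def replay_keynodes(path, n: int | None = None, normalize: bool = True) -> KeyNodeReport:
    """Recompute the bottleneck-hub intersection from a printed top-n table.

    The TSV must carry columns ``hub``, ``degree``, ``bottleneck``,
    ``betweenness`` (one rank per row).  Identifiers are symbol-normalized by
    default so printed variants compare equal.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"hub", "degree", "bottleneck", "betweenness"}
    if not required <= set(table.columns):
        raise PipelineError(
            f"stage replay-keynodes: need columns {sorted(required)}, got {list(table.columns)}"
        )
    if n is not None:
        table = table.head(n)
    norm = netio.normalize_identifier if normalize else str.strip
    hubs = [(norm(h), int(d)) for h, d in zip(table["hub"], table["degree"])]
    bottlenecks = [
        (norm(b), float(v)) for b, v in zip(table["bottleneck"], table["betweenness"])
    ]
    return KeyNodeReport(
        hubs=tuple(hubs),
        bottlenecks=tuple(bottlenecks),
        bottleneck_hubs=tuple(_keynodes.intersect_key_nodes(hubs, bottlenecks)),
    )


def replay_crosstalk(path) -> tuple[pd.DataFrame, str]:
    """Recompute row totals and the key mediator from a printed strength matrix."""
    cells = pd.read_csv(path, sep="\t", index_col=0)
    matrix = _crosstalk.matrix_from_cells(cells)
    return matrix, _crosstalk.key_mediator(matrix)
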
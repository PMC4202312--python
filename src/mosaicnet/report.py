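"""Summaries, diagnostics and pipeline orchestration.

Produces the per-class composite/multicomposite count tables (one row per
Baltimore class, nucleic-acid type or monophyletic group, plus a total
row), the hit-length / E-value diagnostics, and the end-to-end pipeline:
simulate -> build -> detect -> safest -> metrics -> enrich -> report.
Every output file is reproducible from the configuration and its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from . import io_formats, metrics as graph_metrics
from .detect import (
    CompositeCall,
    DetectionParams,
    DetectionResult,
    TripletEvidence,
    call_composites,
    call_multicomposites,
)
from .enrichment import EnrichmentResult, enrichment_table
from .io_formats import (
    BALTIMORE_CLASSES,
    MONOPHYLETIC_CLASSES,
    NA,
    NUCLEIC_ACIDS,
    UNKNOWN,
    SequenceMetadata,
    SequenceRecord,
    export_network,
)
from .network import ComponentPartition, SimilarityNetwork, build_network, \
    connected_components
from .safest import SafestParams, SafestResult, apply_safest
from .synthetic import SyntheticConfig, SyntheticDataset, emit_truth_hits, \
    generate_dataset, write_truth

logger = logging.getLogger(__name__)

#: E-values of 0 (alignments of essentially unbounded significance) are
#: floored here before taking -log10 in diagnostics.
EVALUE_FLOOR = 1e-180


def percent(part: int | float, whole: int | float) -> float:
    """100 * part / whole, rounded half-away-from-zero to one decimal —
    the rounding that reproduces published one-decimal percentages from
    their printed counts."""
    if whole == 0:
        raise ValueError("whole must be > 0")
    if not (0 <= part <= whole):
        raise ValueError("part must satisfy 0 <= part <= whole")
    value = Decimal(part) * 100 / Decimal(whole)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassSummaryRow:
    label: str
    n_sequences: int
    n_composites: int
    pct_composites: float
    n_multicomposites: int
    pct_multicomposites: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_multicomposites <= self.n_composites
                <= self.n_sequences):
            raise ValueError("inconsistent class summary counts")


_CLASS_ORDERS = {
    "baltimore": list(BALTIMORE_CLASSES) + [UNKNOWN],
    "monophyletic": list(MONOPHYLETIC_CLASSES) + [NA],
    "nucleic_acid": list(NUCLEIC_ACIDS) + [UNKNOWN],
}


def class_summary(
    metadata: Mapping[str, SequenceMetadata],
    composites: Iterable[str],
    multicomposites: Iterable[str],
    classification: str,
) -> list[ClassSummaryRow]:
    """Composite/multicomposite counts and percentages per class value,
    plus a Total row; the per-class counts partition the sequence set."""
    if classification not in _CLASS_ORDERS:
        raise ValueError(f"unknown classification {classification!r}")
    composites = set(composites)
    multicomposites = set(multicomposites)
    by_class: dict[str, list[str]] = {}
    for sid, meta in metadata.items():
        by_class.setdefault(getattr(meta, classification), []).append(sid)

    rows: list[ClassSummaryRow] = []
    for label in _CLASS_ORDERS[classification]:
        ids = by_class.get(label)
        if not ids:
            continue
        n_c = sum(1 for s in ids if s in composites)
        n_m = sum(1 for s in ids if s in multicomposites)
        rows.append(ClassSummaryRow(
            label=label,
            n_sequences=len(ids),
            n_composites=n_c,
            pct_composites=percent(n_c, len(ids)),
            n_multicomposites=n_m,
            pct_multicomposites=percent(n_m, len(ids)),
        ))
    total_n = len(metadata)
    rows.append(ClassSummaryRow(
        label="Total",
        n_sequences=total_n,
        n_composites=len(composites & set(metadata)),
        pct_composites=percent(len(composites & set(metadata)), total_n),
        n_multicomposites=len(multicomposites & set(metadata)),
        pct_multicomposites=percent(len(multicomposites & set(metadata)),
                                    total_n),
    ))
    return rows


@dataclass
class Diagnostics:
    r2_all_edges: float
    r2_composite_component_edges: float | None  # None when < 3 such edges
    length_histogram: list[tuple[int, int, int]]  # bin_start, all, cc
    neg_log_evalue_histogram: list[tuple[int, int, int]]


def diagnostics_correlation(
    network: SimilarityNetwork,
    evidence: Iterable[TripletEvidence],
) -> Diagnostics:
    """Squared Pearson correlation of -log10(best E-value) against retained
    hit length, over all edges and over composite-component edges (the b-a
    and b-c edges of passing triplets), plus the two histograms."""
    cc_pairs = set()
    for ev in evidence:
        if ev.passes:
            cc_pairs.add(frozenset((ev.b, ev.a)))
            cc_pairs.add(frozenset((ev.b, ev.c)))

    def collect(edge_filter):
        xs, ys = [], []
        for u, v, data in network.graph.edges(data=True):
            if not edge_filter(frozenset((u, v))):
                continue
            xs.append(-np.log10(max(data["evalue"], EVALUE_FLOOR)))
            ys.append(float(data["aln_length"]))
        return np.array(xs), np.array(ys)

    def r2(xs, ys, which):
        if len(xs) < 3:
            raise ValueError(f"need >= 3 edges for {which} correlation")
        if np.std(xs) == 0 or np.std(ys) == 0:
            raise ValueError(f"degenerate variance in {which} edges")
        return float(np.corrcoef(xs, ys)[0, 1] ** 2)

    x_all, y_all = collect(lambda pair: True)
    x_cc, y_cc = collect(lambda pair: pair in cc_pairs)
    r2_cc = r2(x_cc, y_cc, "composite-component") if len(x_cc) >= 3 else None
    length_bins: dict[int, list[int]] = {}
    evalue_bins: dict[int, list[int]] = {}
    for xs, ys, slot in ((x_all, y_all, 0), (x_cc, y_cc, 1)):
        for x, y in zip(xs, ys):
            lb = int(y // 25) * 25
            eb = int(x // 5) * 5
            length_bins.setdefault(lb, [0, 0])[slot] += 1
            evalue_bins.setdefault(eb, [0, 0])[slot] += 1
    return Diagnostics(
        r2_all_edges=r2(x_all, y_all, "all"),
        r2_composite_component_edges=r2_cc,
        length_histogram=[(b, *length_bins[b]) for b in sorted(length_bins)],
        neg_log_evalue_histogram=[(b, *evalue_bins[b])
                                  for b in sorted(evalue_bins)],
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    safest: SafestParams = field(default_factory=SafestParams)
    do_detect: bool = True
    do_safest: bool = True
    do_metrics: bool = True
    do_enrich: bool = True
    k_pivots: int = 5000
    exact_betweenness_max_n: int = 2000
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "synthetic" in raw:
            sc = dict(raw["synthetic"])
            for key in ("root_length_range", "segment_fraction_range"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            kwargs["synthetic"] = SyntheticConfig(**sc)
        if "detection" in raw:
            kwargs["detection"] = DetectionParams(**raw["detection"])
        if "safest" in raw:
            kwargs["safest"] = SafestParams(**raw["safest"])
        for key in ("do_detect", "do_safest", "do_metrics", "do_enrich",
                    "k_pivots", "exact_betweenness_max_n", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "PipelineConfig":
        from dataclasses import replace
        return replace(self, synthetic=replace(self.synthetic, seed=seed))


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    network: SimilarityNetwork
    components: ComponentPartition
    hits: list = field(default_factory=list)
    detection: DetectionResult | None = None
    multicomposites: DetectionResult | None = None
    safest: SafestResult | None = None
    partition: graph_metrics.CommunityPartition | None = None
    supergraph: object | None = None
    centralities: dict[str, float] | None = None
    contrast: graph_metrics.BetweennessContrast | None = None
    assortativity: dict[str, float] | None = None
    per_class: dict[str, float] | None = None
    enrichment: list[EnrichmentResult] | None = None
    diagnostics: Diagnostics | None = None
    summaries: dict[str, list[ClassSummaryRow]] = field(default_factory=dict)

    @property
    def composite_ids(self) -> set[str]:
        return self.detection.called_ids() if self.detection else set()

    @property
    def multicomposite_ids(self) -> set[str]:
        return self.multicomposites.called_ids() if self.multicomposites \
            else set()


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the toggled stages end to end on a synthetic dataset.

    Disabling detection automatically disables the safest filters (they
    consume its evidence); a notice is logged. Everything is deterministic
    given ``config.synthetic.seed``.
    """
    config = config or PipelineConfig()
    ds = generate_dataset(config.synthetic)
    hits = emit_truth_hits(ds)
    logger.info("simulated %d sequences, %d hits", len(ds.records), len(hits))

    network = build_network(hits, ds.records,
                            threshold=config.detection.build_threshold)
    components = connected_components(network)
    logger.info(
        "network: %d nodes, %d edges, %d clusters, %d singletons",
        network.n_nodes, network.n_edges,
        components.n_clusters, components.n_singletons,
    )
    result = PipelineResult(config=config, dataset=ds, network=network,
                            components=components, hits=hits)

    do_safest = config.do_safest
    if do_safest and not config.do_detect:
        logger.info("safest filters disabled: detection stage is off")
        do_safest = False

    genomes = {r.seq_id: r.genome_id for r in ds.records}
    if config.do_detect:
        result.detection = call_composites(network, config.detection)
        result.multicomposites = call_multicomposites(
            network, result.detection.calls, config.detection)
        logger.info("calls: %d composite, %d multicomposite",
                    len(result.detection.calls),
                    len(result.multicomposites.calls))
        if do_safest:
            result.safest = apply_safest(
                result.detection.calls, result.detection.evidence,
                network, genomes, config.safest, config.detection)
            logger.info("safest: %d composite, %d multicomposite",
                        len(result.safest.composites),
                        len(result.safest.multicomposites))
        for classification in _CLASS_ORDERS:
            result.summaries[classification] = class_summary(
                ds.metadata, result.composite_ids,
                result.multicomposite_ids, classification)
        if network.n_edges >= 3:
            try:
                result.diagnostics = diagnostics_correlation(
                    network, result.detection.evidence)
            except ValueError as exc:
                logger.info("diagnostics skipped: %s", exc)

    if config.do_metrics:
        result.partition = graph_metrics.louvain_first_pass(
            network, seed=config.synthetic.seed)
        result.supergraph = graph_metrics.community_supergraph(
            network, result.partition)
        mode = ("exact" if network.n_nodes <= config.exact_betweenness_max_n
                else "approximate")
        result.centralities = graph_metrics.betweenness(
            network, mode=mode, k_pivots=config.k_pivots,
            seed=config.synthetic.seed)
        label_map = {sid: m.baltimore for sid, m in ds.metadata.items()
                     if m.baltimore != UNKNOWN}
        try:
            result.assortativity = {
                "baltimore": graph_metrics.attribute_assortativity(
                    network, label_map)
            }
            result.per_class = graph_metrics.per_class_assortativity(
                network, label_map)
        except ValueError as exc:
            logger.info("assortativity skipped: %s", exc)
        if config.do_detect and result.composite_ids and \
                len(result.composite_ids) < network.n_nodes:
            try:
                result.contrast = graph_metrics.group_betweenness_contrast(
                    result.centralities, result.composite_ids)
            except ValueError as exc:
                logger.info("betweenness contrast skipped: %s", exc)

    if config.do_enrich and config.do_detect:
        comp = sorted(result.composite_ids)
        rest = sorted(set(genomes) - result.composite_ids)
        if comp and rest:
            result.enrichment = enrichment_table(comp, rest, ds.metadata)

    if config.outdir:
        write_artifacts(result, Path(config.outdir))
    return result


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------

def write_calls_tsv(
    calls: Iterable[CompositeCall], path: Path, safest_ids=None
) -> None:
    with open(path, "w") as fh:
        cols = ["seq_id", "level", "n_supporting_triplets"]
        if safest_ids is not None:
            cols.append("safest")
        fh.write("\t".join(cols) + "\n")
        for c in sorted(calls, key=lambda c: c.seq_id):
            row = [c.seq_id, c.level, str(c.n_supporting_triplets)]
            if safest_ids is not None:
                row.append("1" if c.seq_id in safest_ids else "0")
            fh.write("\t".join(row) + "\n")


def write_evidence_tsv(evidence: Iterable[TripletEvidence], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("b\ta\tc\toverlap_aa\tev_ba\tev_bc\n")
        for ev in sorted(evidence, key=lambda e: (e.b, e.a, e.c)):
            fh.write(f"{ev.b}\t{ev.a}\t{ev.c}\t{ev.overlap_aa}\t"
                     f"{ev.evalue_ba:.6g}\t{ev.evalue_bc:.6g}\n")


def write_summary_tsv(rows: list[ClassSummaryRow], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tn_sequences\tn_composites\tpct_composites\t"
                 "n_multicomposites\tpct_multicomposites\n")
        for r in rows:
            fh.write(f"{r.label}\t{r.n_sequences}\t{r.n_composites}\t"
                     f"{r.pct_composites}\t{r.n_multicomposites}\t"
                     f"{r.pct_multicomposites}\n")


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ds = result.dataset
    io_formats.write_fasta(ds.records, outdir / "sequences.fasta")
    io_formats.write_metadata_table(ds.metadata, outdir / "metadata.tsv")
    write_truth(ds.truth, outdir / "truth.tsv")
    io_formats.write_blast_tab(result.hits, outdir / "hits.tsv")
    export_network(result.network, None, outdir / "network.edges.tsv",
                   format="edge-list")
    node_attrs = {}
    for node in result.network.graph.nodes:
        attrs: dict[str, object] = {}
        if result.detection:
            attrs["composite"] = node in result.composite_ids
            attrs["multicomposite"] = node in result.multicomposite_ids
        if result.partition:
            attrs["community"] = result.partition.labels[node]
        meta = ds.metadata.get(node)
        if meta:
            attrs["baltimore"] = meta.baltimore
        node_attrs[node] = attrs
    export_network(result.network, node_attrs, outdir / "network.graphml",
                   format="graphml")

    if result.detection:
        safest_ids = {c.seq_id for c in result.safest.composites} \
            if result.safest else None
        calls = result.detection.calls + (result.multicomposites.calls
                                          if result.multicomposites else [])
        write_calls_tsv(calls, outdir / "calls.tsv", safest_ids)
        write_evidence_tsv(result.detection.evidence,
                           outdir / "evidence.tsv")
        for classification, rows in result.summaries.items():
            write_summary_tsv(rows,
                              outdir / f"class_summary_{classification}.tsv")

    if result.partition and result.supergraph is not None:
        import networkx as nx
        nx.write_graphml(result.supergraph, str(outdir / "supergraph.graphml"))
        with open(outdir / "node_metrics.tsv", "w") as fh:
            fh.write("seq_id\tcommunity\tbetweenness\tcomposite\n")
            for node in sorted(result.network.graph.nodes):
                bc = (result.centralities or {}).get(node, 0.0)
                fh.write(f"{node}\t{result.partition.labels[node]}\t"
                         f"{bc:.6g}\t"
                         f"{int(node in result.composite_ids)}\n")

    if result.enrichment:
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("category\ta_in\ta_out\tb_in\tb_out\tdirection\t"
                     "p_value\tsignificant\n")
            for e in result.enrichment:
                fh.write(f"{e.category}\t{e.count_a_in}\t{e.count_a_out}\t"
                         f"{e.count_b_in}\t{e.count_b_out}\t{e.direction}\t"
                         f"{e.p_value:.6g}\t{int(e.significant)}\n")

    if result.diagnostics:
        with open(outdir / "diagnostics_histograms.tsv", "w") as fh:
            fh.write("histogram\tbin_start\tall_edges\t"
                     "composite_component_edges\n")
            for b, na, nc in result.diagnostics.length_histogram:
                fh.write(f"hit_length\t{b}\t{na}\t{nc}\n")
            for b, na, nc in result.diagnostics.neg_log_evalue_histogram:
                fh.write(f"neg_log10_evalue\t{b}\t{na}\t{nc}\n")

    summary = {
        "n_sequences": len(ds.records),
        "n_edges": result.network.n_edges,
        "n_clusters": result.components.n_clusters,
        "n_singletons": result.components.n_singletons,
    }
    if result.detection:
        summary["funnel"] = asdict(result.detection.funnel)
        summary["n_composites"] = len(result.detection.calls)
        summary["n_multicomposites"] = len(result.multicomposites.calls) \
            if result.multicomposites else 0
    if result.safest:
        summary["n_safest_composites"] = len(result.safest.composites)
        summary["n_safest_multicomposites"] = len(
            result.safest.multicomposites)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
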
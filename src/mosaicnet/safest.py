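"""The three extra stringency conditions defining the "safest" subset.

Composite calls are vulnerable to annotation artifacts: overlapping genes
annotated twice in one genome, genes artefactually split during annotation,
and genes artefactually fused. Three conservative filters address these in
turn:

1. discard any supporting triplet in which a component comes from the same
   genome as the candidate and is (nearly) fully covered by the retained
   hit — i.e. found embedded in the composite;
2. remove calls supported exclusively by one (surviving) triplet whose two
   components come from a single genome;
3. remove calls whose every network neighbor lies in the candidate's own
   genome (no homolog in any other genome).

"Embedded" is operationalized as same genome plus hit coverage of at least
``embedding_coverage_fraction`` (default 0.95) of the component's length;
protein-level data carries no genome coordinates, so sequence containment
stands in for gene-coordinate overlap.

Filters are applied in the order above and are idempotent; the safest
multicomposites are re-detected on the subgraph induced by the safest
composites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .detect import (
    CompositeCall,
    DetectionParams,
    DetectionResult,
    TripletEvidence,
    TripletFunnel,
    call_multicomposites,
)
from .network import SimilarityNetwork


@dataclass(frozen=True)
class SafestParams:
    embedding_coverage_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.embedding_coverage_fraction <= 1.0):
            raise ValueError("embedding_coverage_fraction must be in (0, 1]")


@dataclass
class SafestResult:
    composites: list[CompositeCall]
    multicomposites: list[CompositeCall]
    surviving_evidence: list[TripletEvidence]
    removed: dict[str, str] = field(default_factory=dict)  # seq_id -> reason


def _genome_of(genomes: Mapping[str, str], seq_id: str) -> str:
    g = genomes.get(seq_id, "")
    if not g:
        raise ValueError(f"missing genome_id for {seq_id!r}")
    return g


def flag_embedded_same_genome(
    evidence: list[TripletEvidence],
    network: SimilarityNetwork,
    genomes: Mapping[str, str],
    params: SafestParams | None = None,
) -> tuple[list[TripletEvidence], list[TripletEvidence]]:
    """Split evidence into (surviving, discarded) by the embedding filter.

    A triplet is discarded when either component shares the candidate's
    genome AND the retained hit covers at least the embedding fraction of
    that component's length.
    """
    params = params or SafestParams()
    keep: list[TripletEvidence] = []
    drop: list[TripletEvidence] = []
    for ev in evidence:
        gb = _genome_of(genomes, ev.b)
        embedded = False
        for comp in (ev.a, ev.c):
            if _genome_of(genomes, comp) != gb:
                continue
            s, e = network.interval_on(ev.b, comp, comp)
            coverage = (e - s + 1) / network.graph.nodes[comp]["length"]
            if coverage >= params.embedding_coverage_fraction:
                embedded = True
                break
        (drop if embedded else keep).append(ev)
    return keep, drop


def flag_single_triplet_single_genome(
    calls: list[CompositeCall],
    evidence: list[TripletEvidence],
    genomes: Mapping[str, str],
) -> tuple[list[CompositeCall], list[CompositeCall]]:
    """Split calls into (kept, removed): a call is removed iff it is
    supported by exactly one surviving triplet whose two components come
    from a single genome. ``evidence`` must be the complete surviving set,
    not a capped sample."""
    by_b: dict[str, list[TripletEvidence]] = {}
    for ev in evidence:
        by_b.setdefault(ev.b, []).append(ev)
    kept: list[CompositeCall] = []
    removed: list[CompositeCall] = []
    for call in calls:
        sup = by_b.get(call.seq_id, [])
        if len(sup) == 1 and (
            _genome_of(genomes, sup[0].a) == _genome_of(genomes, sup[0].c)
        ):
            removed.append(call)
        else:
            kept.append(call)
    return kept, removed


def flag_no_external_homolog(
    calls: list[CompositeCall],
    network: SimilarityNetwork,
    genomes: Mapping[str, str],
) -> tuple[list[CompositeCall], list[CompositeCall]]:
    """Split calls into (kept, removed): removed iff every network neighbor
    of the composite shares its genome (including the no-neighbor edge
    case, which cannot arise for a genuine call but is handled)."""
    kept: list[CompositeCall] = []
    removed: list[CompositeCall] = []
    for call in calls:
        gb = _genome_of(genomes, call.seq_id)
        neighbors = list(network.graph.neighbors(call.seq_id))
        if neighbors and any(_genome_of(genomes, n) != gb for n in neighbors):
            kept.append(call)
        else:
            removed.append(call)
    return kept, removed


def apply_safest(
    calls: list[CompositeCall],
    evidence: list[TripletEvidence],
    network: SimilarityNetwork,
    genomes: Mapping[str, str],
    params: SafestParams | None = None,
    detection_params: DetectionParams | None = None,
) -> SafestResult:
    """Apply the three filters in order and re-detect multicomposites on the
    surviving composite subgraph.

    ``evidence`` must be the complete passing-triplet list from detection
    (filter 2 counts triplets surviving filter 1, so capped samples would
    bias it). Safest composites are always a subset of the input calls.
    """
    params = params or SafestParams()
    surviving, _dropped = flag_embedded_same_genome(
        evidence, network, genomes, params)
    supported_ids = {ev.b for ev in surviving}
    removed: dict[str, str] = {}

    stage1 = []
    for call in calls:
        if call.seq_id in supported_ids:
            stage1.append(call)
        else:
            removed[call.seq_id] = "embedded-same-genome"

    stage2, gone2 = flag_single_triplet_single_genome(
        stage1, surviving, genomes)
    removed.update({c.seq_id: "single-triplet-single-genome" for c in gone2})

    stage3, gone3 = flag_no_external_homolog(stage2, network, genomes)
    removed.update({c.seq_id: "no-external-homolog" for c in gone3})

    multi = call_multicomposites(
        network, stage3, detection_params
    ) if len(stage3) >= 2 else DetectionResult([], [], TripletFunnel())

    return SafestResult(
        composites=stage3,
        multicomposites=multi.calls,
        surviving_evidence=surviving,
        removed=removed,
    )
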
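"""Synthetic gene families with planted fusion events and ground truth.

The generator emulates the similarity structure that composite-gene detection
exploits: unrelated root families whose members diverge by substitutions and
rare indels, fused (composite) sequences joining a prefix from one family to
a suffix from another, and doubly fused (multicomposite) sequences combining
segments of two planted composites so that their parts trace to three or
more families.

Instead of running an aligner, a hit table is derived directly from the
planted ancestry: two sequences sharing a root interval of length ``Lseg``
with combined divergence ``d_pair`` receive a hit with bitscore
``S = lam * Lseg * (1 - 2 * d_pair)`` (clamped at 0) and E-value
``min(1, m * n * 2**-S)`` for sequence lengths ``m`` and ``n`` — a simple
Karlin-Altschul-shaped surrogate, monotone in segment length and divergence.
Optional noise hits between unrelated pairs carry E-values straddling the
network-building threshold to exercise thresholding downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .io_formats import (
    BALTIMORE_CLASSES,
    CATEGORY_ALPHABET,
    MONOPHYLETIC_CLASSES,
    FormatError,
    SequenceMetadata,
    SequenceRecord,
    SimilarityHit,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

LEVEL_COMPONENT = "component"
LEVEL_COMPOSITE = "composite"
LEVEL_MULTICOMPOSITE = "multicomposite"

_CATEGORY_LETTERS = sorted(CATEGORY_ALPHABET)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the validation conditions used throughout: 30 unrelated
    families of 10 members each, 20 planted composites and 5 multicomposites,
    15% per-site substitution divergence, rare indels (1% of sites), and
    segment fractions chosen so every planted segment is at least ~100 aa.
    """

    n_families: int = 30
    members_per_family: int = 10
    root_length_range: tuple[int, int] = (300, 600)
    divergence: float = 0.15
    indel_rate: float = 0.01
    n_composites: int = 20
    n_multicomposites: int = 5
    segment_fraction_range: tuple[float, float] = (0.35, 0.65)
    n_genomes: int = 50
    noise_hit_rate: float = 0.01
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_families", "members_per_family", "n_composites",
                     "n_multicomposites", "n_genomes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.segment_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("segment_fraction_range must lie within (0, 1)")
        if not (0.0 <= self.divergence < 0.5):
            raise ValueError("divergence must lie in [0, 0.5)")
        if self.root_length_range[0] > self.root_length_range[1] or \
                self.root_length_range[0] <= 0:
            raise ValueError("invalid root_length_range")


@dataclass(frozen=True)
class AncestrySegment:
    """One collinear block tracing an interval of a sequence to an interval
    of a family root (both 1-based inclusive, equal length)."""

    family_id: str
    seq_start: int
    seq_end: int
    root_start: int
    root_end: int

    def __post_init__(self) -> None:
        if self.seq_start > self.seq_end or self.root_start > self.root_end:
            raise ValueError("unordered ancestry interval")
        if self.seq_end - self.seq_start != self.root_end - self.root_start:
            raise ValueError("ancestry block is not collinear")


@dataclass
class SyntheticTruth:
    """Planted ancestry and composite labels for every generated sequence."""

    segments: dict[str, list[AncestrySegment]] = field(default_factory=dict)
    levels: dict[str, str] = field(default_factory=dict)

    def families_of(self, seq_id: str) -> set[str]:
        return {s.family_id for s in self.segments[seq_id]}

    def composites(self) -> set[str]:
        """Sequences planted as composite, including multicomposites."""
        return {
            s for s, lv in self.levels.items()
            if lv in (LEVEL_COMPOSITE, LEVEL_MULTICOMPOSITE)
        }

    def multicomposites(self) -> set[str]:
        return {s for s, lv in self.levels.items() if lv == LEVEL_MULTICOMPOSITE}


@dataclass
class SyntheticDataset:
    """Records + metadata + truth, plus the family roots and per-member
    alignment blocks needed to plant further events or derive hits."""

    config: SyntheticConfig
    records: list[SequenceRecord]
    metadata: dict[str, SequenceMetadata]
    truth: SyntheticTruth
    roots: dict[str, str]  # family_id -> root residues
    _primary_family: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Member generation
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))

def _substitute(rng: np.random.Generator, residue: str) -> str:
    others = AMINO_ACIDS.replace(residue, "")
    return others[rng.integers(len(others))]


def _mutate_member(
    root: str, d: float, indel_rate: float, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int, int, int]]]:
    """Derive one member from a root: i.i.d. substitutions at rate ``d`` and
    geometric-length indels at ``indel_rate`` per site.

    Returns the residues and the collinear alignment blocks
    (root_start, root_end, seq_start, seq_end), 1-based inclusive. Indels are
    rare by default so the root<->member mapping stays piecewise-linear and
    exact.
    """
    out: list[str] = []
    blocks: list[tuple[int, int, int, int]] = []
    block_root = block_seq = 0  # 1-based starts of the open block; 0 = closed
    i = 0  # 0-based root index
    L = len(root)
    while i < L:
        if indel_rate > 0 and rng.random() < indel_rate:
            g = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # deletion of g root positions
                if block_root:
                    blocks.append((block_root, i, block_seq, len(out)))
                    block_root = 0
                i += g
                continue
            else:  # insertion of g novel residues
                if block_root:
                    blocks.append((block_root, i, block_seq, len(out)))
                    block_root = 0
                out.extend(_random_protein(rng, g))
        res = root[i]
        if d > 0 and rng.random() < d:
            res = _substitute(rng, res)
        out.append(res)
        if not block_root:
            block_root, block_seq = i + 1, len(out)
        i += 1
    if block_root:
        blocks.append((block_root, L, block_seq, len(out)))
    if not out:  # pathological all-deleted draw; fall back to the root copy
        return root, [(1, L, 1, L)]
    return "".join(out), blocks


def _clip_segments(
    segments: list[AncestrySegment], lo: int, hi: int, shift: int
) -> list[AncestrySegment]:
    """Restrict ancestry blocks to seq window [lo, hi] and shift seq
    coordinates by ``shift`` (new_pos = old_pos + shift)."""
    out = []
    for s in segments:
        a, b = max(s.seq_start, lo), min(s.seq_end, hi)
        if a > b:
            continue
        out.append(
            AncestrySegment(
                family_id=s.family_id,
                seq_start=a + shift,
                seq_end=b + shift,
                root_start=s.root_start + (a - s.seq_start),
                root_end=s.root_end - (s.seq_end - b),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset: families, members, planted composites and
    multicomposites, genome assignment and class labels.

    Root families are independent uniform-random amino-acid strings, hence
    mutually unrelated with overwhelming probability. Sequences are assigned
    round-robin to genomes; class labels follow the primary (first) planted
    family so that within-family edges are class-assortative. Deterministic
    given ``config.seed``.
    """
    if config.n_composites > 0 and config.n_families < 2:
        raise ValueError("planting composites requires at least 2 families")
    if config.n_multicomposites > 0 and config.n_composites < 2:
        raise ValueError("planting multicomposites requires >= 2 composites")
    rng = np.random.default_rng(config.seed)

    roots: dict[str, str] = {}
    lo, hi = config.root_length_range
    for f in range(config.n_families):
        fam = f"fam{f:03d}"
        roots[fam] = _random_protein(rng, int(rng.integers(lo, hi + 1)))

    ds = SyntheticDataset(
        config=config, records=[], metadata={}, truth=SyntheticTruth(), roots=roots
    )
    for fam in roots:
        for m in range(config.members_per_family):
            seq_id = f"{fam}_m{m:02d}"
            residues, blocks = _mutate_member(
                roots[fam], config.divergence, config.indel_rate, rng
            )
            _add_sequence(
                ds,
                seq_id,
                residues,
                [AncestrySegment(fam, bs, be, rs, re_)
                 for rs, re_, bs, be in blocks],
                LEVEL_COMPONENT,
            )

    plant_composites(ds, config, rng)
    _assign_metadata(ds)
    return ds


def _add_sequence(
    ds: SyntheticDataset,
    seq_id: str,
    residues: str,
    segments: list[AncestrySegment],
    level: str,
) -> None:
    ds.records.append(SequenceRecord(seq_id=seq_id, length=len(residues),
                                     residues=residues))
    ds.truth.segments[seq_id] = sorted(segments, key=lambda s: s.seq_start)
    ds.truth.levels[seq_id] = level
    ds._primary_family[seq_id] = segments[0].family_id


def plant_composites(
    ds: SyntheticDataset,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Plant fused and doubly fused sequences, recording exact junctions.

    Each composite is a prefix fraction of a fresh member of one family
    concatenated with a suffix fraction of a fresh member of a second
    family. Each multicomposite concatenates a prefix of one planted
    composite (spanning its whole first segment plus part of its second)
    with a suffix of another composite from a disjoint family pair, so its
    parts trace to at least three families. The first ``2 * n_multicomposites``
    composites are built on mutually disjoint family pairs to guarantee the
    multicomposite construction is possible.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if config.n_composites == 0:
        return ds
    fams = list(ds.roots)
    order = list(rng.permutation(len(fams)))
    n_reserved = 4 * config.n_multicomposites
    if n_reserved > len(fams) or \
            config.n_composites < 2 * config.n_multicomposites:
        raise ValueError(
            "not enough disjoint family pairs for the requested "
            "multicomposites; raise n_families or n_composites"
        )
    # Donor-role discipline keeps truth labels and detectable patterns in
    # agreement: a family donates prefixes only or suffixes only, so two
    # composites sharing a family always share an overlapping root segment
    # (and hence an edge), never disjoint ends of the same root — disjoint
    # ends would make plain members of that family genuine (fission-like)
    # bridges. Families reserved for multicomposite sources are used by
    # exactly one composite each for the same reason.
    pairs: list[tuple[str, str]] = []
    used: set[frozenset[str]] = set()
    for k in range(2 * config.n_multicomposites):
        pair = (fams[order[2 * k]], fams[order[2 * k + 1]])
        pairs.append(pair)
        used.add(frozenset(pair))
    n_extra = config.n_composites - 2 * config.n_multicomposites
    free = [fams[i] for i in order[n_reserved:]]
    if n_extra > 0 and len(free) < 2:
        raise ValueError(
            "no unreserved families left for additional composites; "
            "raise n_families"
        )
    role: dict[str, str] = {}
    tries = 0
    while len(pairs) < config.n_composites:
        tries += 1
        if tries > 1000 * config.n_composites:
            raise ValueError("exhausted compatible family pairs; "
                             "raise n_families")
        i, j = rng.choice(len(free), size=2, replace=False)
        f1, f2 = free[i], free[j]
        if role.get(f1) == "suffix" or role.get(f2) == "prefix":
            f1, f2 = f2, f1
        if role.get(f1) == "suffix" or role.get(f2) == "prefix" or \
                frozenset((f1, f2)) in used:
            continue
        role[f1], role[f2] = "prefix", "suffix"
        used.add(frozenset((f1, f2)))
        pairs.append((f1, f2))

    flo, fhi = config.segment_fraction_range
    composite_ids: list[str] = []
    junctions: dict[str, int] = {}
    for k, (f1, f2) in enumerate(pairs):
        m1, b1 = _mutate_member(ds.roots[f1], config.divergence,
                                config.indel_rate, rng)
        m2, b2 = _mutate_member(ds.roots[f2], config.divergence,
                                config.indel_rate, rng)
        u1 = rng.uniform(flo, fhi)
        u2 = rng.uniform(flo, fhi)
        k1 = max(1, round(u1 * len(m1)))
        k2 = max(1, round(u2 * len(m2)))
        seg1 = _clip_segments(
            [AncestrySegment(f1, bs, be, rs, re_) for rs, re_, bs, be in b1],
            1, k1, 0)
        seg2 = _clip_segments(
            [AncestrySegment(f2, bs, be, rs, re_) for rs, re_, bs, be in b2],
            len(m2) - k2 + 1, len(m2), k1 - (len(m2) - k2))
        seq_id = f"comp{k:03d}"
        _add_sequence(ds, seq_id, m1[:k1] + m2[len(m2) - k2:],
                      seg1 + seg2, LEVEL_COMPOSITE)
        composite_ids.append(seq_id)
        junctions[seq_id] = k1

    for k in range(config.n_multicomposites):
        ca, cb = composite_ids[2 * k], composite_ids[2 * k + 1]
        ra = next(r for r in ds.records if r.seq_id == ca)
        rb = next(r for r in ds.records if r.seq_id == cb)
        ja, jb = junctions[ca], junctions[cb]
        cut1 = ja + max(1, (ra.length - ja) // 2)  # all of f1 + half of f2
        cut2 = max(1, jb // 2)                     # half of f3 + all of f4
        seg_a = _clip_segments(ds.truth.segments[ca], 1, cut1, 0)
        seg_b = _clip_segments(ds.truth.segments[cb], cut2 + 1, rb.length,
                               cut1 - cut2)
        seq_id = f"multi{k:03d}"
        _add_sequence(
            ds, seq_id,
            ra.residues[:cut1] + rb.residues[cut2:],
            seg_a + seg_b, LEVEL_MULTICOMPOSITE,
        )
    return ds


def _assign_metadata(ds: SyntheticDataset) -> None:
    fam_index = {fam: i for i, fam in enumerate(ds.roots)}
    for i, rec in enumerate(ds.records):
        fi = fam_index[ds._primary_family[rec.seq_id]]
        baltimore = BALTIMORE_CLASSES[fi % 7]
        nucleic = "DNA" if baltimore in ("I", "II", "VII") else "RNA"
        genome = f"g{i % ds.config.n_genomes:03d}" if ds.config.n_genomes else "g0"
        ds.metadata[rec.seq_id] = SequenceMetadata(
            seq_id=rec.seq_id,
            genome_id=genome,
            baltimore=baltimore,
            monophyletic=MONOPHYLETIC_CLASSES[fi % 5],
            nucleic_acid=nucleic,
            categories=frozenset(_CATEGORY_LETTERS[fi % 25]),
        )
        ds.records[i] = replace(rec, genome_id=genome)


# ---------------------------------------------------------------------------
# Truth-derived hit table
# ---------------------------------------------------------------------------

def emit_truth_hits(
    ds: SyntheticDataset,
    lam: float = 2.0,
    noise_hit_rate: float | None = None,
    noise_seed: int | None = None,
) -> list[SimilarityHit]:
    """Derive the all-vs-all hit table from planted ancestry.

    For every ordered pair of sequences sharing ancestry on a common
    family-root interval, one hit per shared family is emitted, with
    coordinates mapped through the alignment blocks and statistics from the
    surrogate E-value model (module docstring). Pairs from unrelated
    families get no hit except explicit noise hits, whose E-values fall in
    [1e-6, 1e-5) — just around the network-building threshold.
    """
    if noise_hit_rate is None:
        noise_hit_rate = ds.config.noise_hit_rate
    rng = np.random.default_rng(
        ds.config.seed + 2 if noise_seed is None else noise_seed)
    d = ds.config.divergence
    lengths = {r.seq_id: r.length for r in ds.records}

    for sid, segs in ds.truth.segments.items():
        prev_end = 0
        for s in segs:
            if s.seq_start <= prev_end:
                raise ValueError(
                    f"contradictory overlapping truth segments on {sid!r}")
            prev_end = s.seq_end
            if s.seq_end > lengths[sid]:
                raise ValueError(f"truth segment beyond sequence end on {sid!r}")

    by_family: dict[str, list[str]] = {}
    for sid, segs in ds.truth.segments.items():
        for fam in {s.family_id for s in segs}:
            by_family.setdefault(fam, []).append(sid)

    hits: list[SimilarityHit] = []
    related: set[frozenset[str]] = set()
    for fam, sids in by_family.items():
        sids = sorted(sids)
        for i in range(len(sids)):
            for j in range(i + 1, len(sids)):
                x, y = sids[i], sids[j]
                related.add(frozenset((x, y)))
                hit = _pair_hit(ds, fam, x, y, d, lam, lengths)
                if hit is not None:
                    hits.append(hit)
                    hits.append(_flip(hit))

    if noise_hit_rate > 0:
        ids = sorted(lengths)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pair = frozenset((ids[i], ids[j]))
                if pair in related:
                    continue
                if rng.random() < noise_hit_rate:
                    hits.append(_noise_hit(rng, ids[i], ids[j], lengths))
    return hits


def _pair_hit(ds, fam, x, y, d, lam, lengths) -> SimilarityHit | None:
    sx = [s for s in ds.truth.segments[x] if s.family_id == fam]
    sy = [s for s in ds.truth.segments[y] if s.family_id == fam]
    rx = (min(s.root_start for s in sx), max(s.root_end for s in sx))
    ry = (min(s.root_start for s in sy), max(s.root_end for s in sy))
    lo, hi = max(rx[0], ry[0]), min(rx[1], ry[1])
    if lo > hi:
        return None
    ix = _map_root_interval(sx, lo, hi)
    iy = _map_root_interval(sy, lo, hi)
    if ix is None or iy is None:
        return None
    lseg = hi - lo + 1
    d_pair = d + d  # both members diverged independently from the root
    score = max(0.0, lam * lseg * (1.0 - 2.0 * d_pair))
    evalue = min(1.0, lengths[x] * lengths[y] * 2.0 ** (-score))
    return SimilarityHit(
        query_id=x, subject_id=y, evalue=evalue, bitscore=score,
        q_start=ix[0], q_end=ix[1], s_start=iy[0], s_end=iy[1],
        aln_length=lseg,
    )


def _map_root_interval(segs, lo, hi) -> tuple[int, int] | None:
    """Map a root interval onto sequence coordinates through the blocks;
    returns the envelope of the mapped positions."""
    pos = []
    for s in segs:
        a, b = max(s.root_start, lo), min(s.root_end, hi)
        if a > b:
            continue
        pos.append(s.seq_start + (a - s.root_start))
        pos.append(s.seq_start + (b - s.root_start))
    if not pos:
        return None
    return min(pos), max(pos)


def _flip(h: SimilarityHit) -> SimilarityHit:
    return SimilarityHit(
        query_id=h.subject_id, subject_id=h.query_id, evalue=h.evalue,
        bitscore=h.bitscore, q_start=h.s_start, q_end=h.s_end,
        s_start=h.q_start, s_end=h.q_end, aln_length=h.aln_length,
    )


def _noise_hit(rng, x, y, lengths) -> SimilarityHit:
    w = 30
    qlen, slen = lengths[x], lengths[y]
    qs = int(rng.integers(1, max(2, qlen - w + 2)))
    ss = int(rng.integers(1, max(2, slen - w + 2)))
    return SimilarityHit(
        query_id=x, subject_id=y,
        evalue=float(rng.uniform(1e-6, 1e-5)),
        bitscore=float(rng.uniform(20, 35)),
        q_start=qs, q_end=min(qlen, qs + w - 1),
        s_start=ss, s_end=min(slen, ss + w - 1),
        aln_length=w,
    )


# ---------------------------------------------------------------------------
# Truth TSV round trip
# ---------------------------------------------------------------------------

_TRUTH_HEADER = ("seq_id", "level", "family_id", "seq_start", "seq_end",
                 "root_start", "root_end")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_HEADER) + "\n")
        for sid in sorted(truth.segments):
            for s in truth.segments[sid]:
                fh.write(
                    f"{sid}\t{truth.levels[sid]}\t{s.family_id}\t"
                    f"{s.seq_start}\t{s.seq_end}\t{s.root_start}\t{s.root_end}\n"
                )


def read_truth(path: str | Path) -> SyntheticTruth:
    truth = SyntheticTruth()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TRUTH_HEADER:
            raise FormatError(f"{path}: unexpected truth header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise FormatError(f"{path}, line {lineno}: expected 7 columns")
            sid, level, fam = parts[0], parts[1], parts[2]
            try:
                seg = AncestrySegment(
                    family_id=fam,
                    seq_start=int(parts[3]), seq_end=int(parts[4]),
                    root_start=int(parts[5]), root_end=int(parts[6]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
            truth.segments.setdefault(sid, []).append(seg)
            truth.levels[sid] = level
    return truth
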
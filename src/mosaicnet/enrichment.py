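"""Functional-category composition and Fisher exact enrichment.

Sequences carry zero or more one-letter COG/KOG functional categories;
unannotated sequences are excluded from all functional analyses. For
composition plots a sequence with m categories is redistributed evenly,
contributing 1/m to each (fractional mode); for count tables it contributes
a full count to each (full mode).

Enrichment of a category in one gene set against another tests the 2x2
table (in category vs every other category) x (set A vs set B) with a
two-sided Fisher exact test — the two-sided p sums all hypergeometric
probabilities not exceeding the observed table's. Family-wise control over
the m categories uses the conservative Bonferroni rule: significant iff
p < alpha / m, computed exactly. When set A is a subset of a larger set
(e.g. composites within all viral sequences), the caller should pass the
complement as set B so the table is well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import fisher_exact

from .io_formats import CATEGORY_ALPHABET, SequenceMetadata

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    count_a_in: int
    count_a_out: int
    count_b_in: int
    count_b_out: int
    direction: str  # "enriched" | "depleted" | "equal"
    p_value: float
    significant: bool
    degenerate: bool = False  # zero-margin table

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.count_a_in, self.count_a_out),
                (self.count_b_in, self.count_b_out))


def category_weights(
    metadata: Mapping[str, SequenceMetadata], mode: str = "fractional"
) -> dict[str, dict[str, float]]:
    """Per-sequence category weights; unannotated sequences are excluded
    entirely (their weight dict is absent, not empty-summing)."""
    if mode not in ("fractional", "full"):
        raise ValueError(f"unknown weights mode {mode!r}")
    out: dict[str, dict[str, float]] = {}
    for sid, meta in metadata.items():
        cats = meta.categories
        if not cats:
            continue
        w = 1.0 / len(cats) if mode == "fractional" else 1.0
        out[sid] = {c: w for c in sorted(cats)}
    return out


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table; a zero-margin table is
    degenerate with p = 1."""
    (a, b), (c, d) = table
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_category_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    category: str,
    metadata: Mapping[str, SequenceMetadata],
    weights_mode: str = "full",
    alpha: float = DEFAULT_ALPHA,
    m_categories: int = 1,
) -> EnrichmentResult:
    """Test one category in set A against set B (category vs the
    combination of every other category), over annotated sequences only."""
    if weights_mode != "full":
        raise ValueError("Fisher tables require integer counts (full mode)")
    a_in = a_out = b_in = b_out = 0
    for sid in set_a:
        cats = metadata[sid].categories
        if not cats:
            continue
        if category in cats:
            a_in += 1
        else:
            a_out += 1
    for sid in set_b:
        cats = metadata[sid].categories
        if not cats:
            continue
        if category in cats:
            b_in += 1
        else:
            b_out += 1
    degenerate = min(a_in + a_out, b_in + b_out, a_in + b_in, a_out + b_out) == 0
    p = fisher_two_sided(((a_in, a_out), (b_in, b_out)))
    prop_a = a_in / (a_in + a_out) if a_in + a_out else 0.0
    prop_b = b_in / (b_in + b_out) if b_in + b_out else 0.0
    if prop_a > prop_b:
        direction = "enriched"
    elif prop_a < prop_b:
        direction = "depleted"
    else:
        direction = "equal"
    return EnrichmentResult(
        category=category,
        count_a_in=a_in, count_a_out=a_out,
        count_b_in=b_in, count_b_out=b_out,
        direction=direction,
        p_value=p,
        significant=(not degenerate) and p < alpha / m_categories,
        degenerate=degenerate,
    )


def enrichment_table(
    set_a: Iterable[str],
    set_b: Iterable[str],
    metadata: Mapping[str, SequenceMetadata],
    categories: Iterable[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """One two-sided test per category with Bonferroni control at
    alpha / m over the m tested categories; both enrichment and depletion
    directions are reported."""
    cats = sorted(categories) if categories is not None \
        else sorted(CATEGORY_ALPHABET)
    if not cats:
        raise ValueError("at least one category required")
    set_a = list(set_a)
    set_b = list(set_b)
    return [
        fisher_category_test(
            set_a, set_b, c, metadata,
            alpha=alpha, m_categories=len(cats),
        )
        for c in cats
    ]
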
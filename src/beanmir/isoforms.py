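"""Detection, filtering and classification of miRNA sequence/length variants
(isomiRs).

A residual tag (no exact reference match) is matched against the mature
reference set by ungapped alignment allowing at most two substitutions in
the overlap and terminal offsets of at most two nucleotides per end (length
differences and small shifts are offsets, not mismatches).  Variants then
pass an abundance filter — at least 1.5x the total reads of their reference
miRNA, or, when the reference was not observed at all, only the single most
abundant variant — and are classified as length variants (no substitution),
conserved variants (substitutions, family already conserved) or
non-conserved variants.  Families whose retained variants are sufficiently
abundant are promoted into the conserved family list used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .conserved import MatureRef, offset_alignment_subs
from .core_io import LibrarySet, Tag

PREFILTER_MIN_TOTAL = 10      # strict: total across libraries must exceed this
ABUNDANCE_RATIO = 1.5         # inclusive: variant total >= ratio * reference total
PROMOTION_MIN_TOTAL = 1000

LENGTH, CONSERVED, NON_CONSERVED = "length", "conserved", "non_conserved"


@dataclass
class VariantCall:
    """A tag fuzzily matched to a reference miRNA."""

    variant: str
    ref: MatureRef
    n_subs: int
    offset5: int
    offset3: int
    counts: dict[str, int] = field(default_factory=dict)
    var_class: str | None = None
    retained: bool | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def prefilter_tags(tags: Iterable[Tag],
                   min_total: int = PREFILTER_MIN_TOTAL) -> list[Tag]:
    """Keep residual tags whose summed count across libraries exceeds
    ``min_total`` (strict)."""
    return [t for t in tags if t.total() > min_total]


def fuzzy_match(tag: Tag | str, refs: Sequence[MatureRef],
                ref_totals: Mapping[str, int] | None = None,
                max_subs: int = 2, max_offset: int = 2) -> VariantCall | None:
    """Best ungapped variant alignment of a tag over all references.

    Minimizes substitutions (<= ``max_subs``) over all alignments with
    terminal offsets <= ``max_offset`` per end; ties broken by smaller total
    offset, then by the reference with more observed reads, then by
    reference name.  Returns None when no reference qualifies.
    """
    seq = tag.sequence if isinstance(tag, Tag) else tag
    counts = dict(tag.counts) if isinstance(tag, Tag) else {}
    totals = ref_totals or {}
    best = None
    best_key = None
    for ref in refs:
        if seq == ref.sequence:
            continue  # exact hits are annotation, never variants
        aln = offset_alignment_subs(seq, ref.sequence, max_offset)
        if aln is None:
            continue
        subs, o5, o3 = aln
        if subs > max_subs:
            continue
        key = (subs, abs(o5) + abs(o3), -totals.get(ref.name, 0), ref.name)
        if best_key is None or key < best_key:
            best_key = key
            best = VariantCall(seq, ref, subs, o5, o3, counts)
    return best


def abundance_filter(variants: Iterable[VariantCall],
                     ref_totals: Mapping[str, int],
                     ratio: float = ABUNDANCE_RATIO) -> list[VariantCall]:
    """Retain variants clearly more abundant than their reference miRNA.

    Reference observed (total > 0): retained iff variant total >= ratio x
    reference total (inclusive).  Reference unobserved: only the single
    highest-total variant of that reference is retained.
    """
    by_ref: dict[str, list[VariantCall]] = {}
    for v in variants:
        by_ref.setdefault(v.ref.name, []).append(v)
    retained: list[VariantCall] = []
    for name, group in by_ref.items():
        ref_total = ref_totals.get(name, 0)
        if ref_total > 0:
            for v in group:
                v.retained = v.total >= ratio * ref_total
        else:
            top = max(group, key=lambda v: (v.total, v.variant))
            for v in group:
                v.retained = v is top
        retained.extend(v for v in group if v.retained)
    return retained


def classify_variant(call: VariantCall, conserved_families: set[str]) -> str:
    """Three-way classification of a retained variant."""
    if call.n_subs == 0:
        call.var_class = LENGTH
    elif call.ref.family in conserved_families:
        call.var_class = CONSERVED
    else:
        call.var_class = NON_CONSERVED
    return call.var_class


def promote_families(retained: Iterable[VariantCall],
                     conserved_families: set[str],
                     min_total: float = PROMOTION_MIN_TOTAL) -> set[str]:
    """Promote families absent from the conserved list whose retained
    variants together reach ``min_total`` reads across libraries."""
    totals: dict[str, int] = {}
    for v in retained:
        if v.ref.family not in conserved_families:
            totals[v.ref.family] = totals.get(v.ref.family, 0) + v.total
    return {fam for fam, t in totals.items() if t >= min_total}


def call_isomirs(residual: LibrarySet | Iterable[Tag],
                 refs: Sequence[MatureRef],
                 ref_totals: Mapping[str, int],
                 conserved_families: set[str],
                 min_total: int = PREFILTER_MIN_TOTAL,
                 ratio: float = ABUNDANCE_RATIO,
                 ) -> tuple[list[VariantCall], list[VariantCall]]:
    """The full isomiR chain: prefilter -> fuzzy match -> abundance filter ->
    classify.  Returns (retained and classified calls, all candidate calls)."""
    tags = residual.sorted_tags() if isinstance(residual, LibrarySet) else list(residual)
    candidates: list[VariantCall] = []
    for tag in prefilter_tags(tags, min_total):
        call = fuzzy_match(tag, refs, ref_totals)
        if call is not None:
            candidates.append(call)
    retained = abundance_filter(candidates, ref_totals, ratio)
    for call in retained:
        classify_variant(call, conserved_families)
    return retained, candidates


def variant_table_rows(calls: Sequence[VariantCall],
                       libraries: Sequence[str]) -> list[dict[str, object]]:
    """Rows for the isomiR report TSV, sorted by class then total."""
    order = {LENGTH: 0, NON_CONSERVED: 1, CONSERVED: 2}
    rows = []
    for c in sorted(calls, key=lambda c: (order.get(c.var_class, 3), -c.total, c.variant)):
        row: dict[str, object] = {
            "variant": c.variant, "reference": c.ref.name, "class": c.var_class,
            "subs": c.n_subs, "offset5": c.offset5, "offset3": c.offset3,
        }
        for lib in libraries:
            row[lib] = c.counts.get(lib, 0)
        row["total"] = c.total
        rows.append(row)
    return rows
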
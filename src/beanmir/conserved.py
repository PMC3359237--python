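"""Non-miRNA filtering, exact conserved-miRNA annotation, the two-library /
15-read conservation filter, family locus prediction, and cross-species
locus-count correlation.

Annotation is by exact sequence identity against a deduplicated mature /
mature-star reference set (a hash lookup; equivalent to requiring alignment
hits of identical length and composition).  The conservation filter keeps a
miRNA only when it was detected in at least two organ libraries and totals at
least 15 reads across all libraries; discarded hits are kept in a side table
because precursor evidence may later rescue them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import LibrarySet, SequenceRecord, Tag

MIN_LIBRARIES = 2
MIN_TOTAL_READS = 15

_FAMILY_RE = re.compile(r"mir[-_ ]?(\d+)", re.IGNORECASE)


def family_from_name(name: str) -> str:
    """Extract the family label from a miRNA name (``ath-miR156a`` -> ``156``)."""
    m = _FAMILY_RE.search(name)
    if not m:
        raise ValueError(f"cannot parse family from miRNA name {name!r}")
    return m.group(1)


@dataclass(frozen=True)
class MatureRef:
    """A reference mature (or mature-star) miRNA."""

    name: str
    sequence: str
    family: str = ""
    is_star: bool = False

    def __post_init__(self):
        if not self.family:
            object.__setattr__(self, "family", family_from_name(self.name))


@dataclass
class AnnotationHit:
    """A tag annotated as exactly equal to a reference miRNA."""

    ref: MatureRef
    counts: dict[str, int] = field(default_factory=dict)
    kept: bool | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def libraries_detected(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)


def dedupe_refs(refs: Iterable[MatureRef]) -> list[MatureRef]:
    """One canonical entry per distinct sequence (first name wins)."""
    seen: dict[str, MatureRef] = {}
    for ref in refs:
        seen.setdefault(ref.sequence, ref)
    return list(seen.values())


def filter_ncrna(libset: LibrarySet, ncrna_db: Sequence[SequenceRecord],
                 mature_refs: Sequence[MatureRef] | None = None,
                 ) -> tuple[LibrarySet, list[Tag]]:
    """Remove tags that perfectly match (as full-length fragments) known
    non-miRNA ncRNAs.

    A tag is removed iff its full extent occurs verbatim inside an ncRNA
    entry; a single mismatch retains the tag.  If ``mature_refs`` is given,
    any ncRNA entry equal to a reference mature sequence is a configuration
    error (the ncRNA set must have miRNAs removed beforehand).
    """
    if mature_refs is not None:
        mature_seqs = {r.sequence for r in mature_refs}
        clash = [e.id for e in ncrna_db if e.sequence in mature_seqs]
        if clash:
            raise ValueError(
                f"ncRNA database shares sequences with the mature reference set: {clash}")
    entries = [e.sequence for e in ncrna_db]
    removed: list[Tag] = []
    kept: list[Tag] = []
    for tag in libset.sorted_tags():
        if any(tag.sequence in entry for entry in entries):
            removed.append(tag)
        else:
            kept.append(tag)
    return LibrarySet(libset.libraries, kept), removed


def annotate_exact(libset: LibrarySet, refs: Sequence[MatureRef],
                   ) -> tuple[list[AnnotationHit], LibrarySet]:
    """Annotate tags exactly equal to a reference; return hits + residual pool.

    References must be deduplicated by sequence (duplicates are an error).
    Annotated tags are removed from the residual pool, so annotation and the
    residual partition the input tag set.
    """
    by_seq: dict[str, MatureRef] = {}
    for ref in refs:
        if ref.sequence in by_seq:
            raise ValueError(
                f"duplicate reference sequence: {by_seq[ref.sequence].name} / {ref.name}")
        by_seq[ref.sequence] = ref
    hits: list[AnnotationHit] = []
    residual: list[Tag] = []
    for tag in libset.sorted_tags():
        ref = by_seq.get(tag.sequence)
        if ref is None:
            residual.append(tag)
        else:
            hits.append(AnnotationHit(ref, dict(tag.counts)))
    return hits, LibrarySet(libset.libraries, residual)


def conservation_filter(hits: Iterable[AnnotationHit],
                        min_libraries: int = MIN_LIBRARIES,
                        min_total: int = MIN_TOTAL_READS,
                        ) -> tuple[list[AnnotationHit], list[AnnotationHit]]:
    """Partition hits into kept / discarded by the conservation rule.

    Kept iff detected in >= ``min_libraries`` organ libraries AND total reads
    >= ``min_total`` (both inclusive).  Pure function of the counts; running
    it on its own output is the identity on the kept side.
    """
    kept, discarded = [], []
    for hit in hits:
        hit.kept = (hit.libraries_detected >= min_libraries
                    and hit.total >= min_total)
        (kept if hit.kept else discarded).append(hit)
    return kept, discarded


def offset_alignment_subs(a: str, b: str, max_offset: int = 2,
                          ) -> tuple[int, int, int] | None:
    """Best ungapped terminal-offset alignment of ``a`` against ``b``.

    Returns (n_subs, offset5, offset3) minimizing substitutions in the
    overlap, ties broken by smaller |offset5|+|offset3|.  Offsets are signed,
    positive when ``a`` extends beyond ``b`` at that end; both ends capped at
    ``max_offset``.  None when no alignment satisfies the caps.
    """
    best: tuple[int, int, int] | None = None
    la, lb = len(a), len(b)
    for o5 in range(-max_offset, max_offset + 1):
        # o5 > 0: a has o5 extra 5' bases; alignment puts a[o5] over b[0]
        o3 = (la - o5) - lb
        if abs(o3) > max_offset:
            continue
        astart = max(o5, 0)
        bstart = max(-o5, 0)
        n = min(la - astart, lb - bstart)
        if n <= 0:
            continue
        subs = sum(1 for i in range(n) if a[astart + i] != b[bstart + i])
        cand = (subs, o5, o3)
        if best is None or (subs, abs(o5) + abs(o3)) < (best[0], abs(best[1]) + abs(best[2])):
            best = cand
    return best


def same_locus(a: str, b: str, max_offset: int = 2) -> bool:
    """Zero-substitution offset alignment: one sequence is an extension,
    truncation or small shift of the other with no internal mismatch."""
    hit = offset_alignment_subs(a, b, max_offset)
    return hit is not None and hit[0] == 0


def predict_loci(sequences_by_family: dict[str, Sequence[str]],
                 max_offset: int = 2) -> dict[str, int]:
    """Predicted locus count per family: equivalence classes of mature
    sequences under the zero-substitution offset relation (transitive
    closure, so the result is invariant to input order)."""
    out: dict[str, int] = {}
    for family, seqs in sequences_by_family.items():
        seqs = sorted(set(seqs))
        if not seqs:
            continue
        parent = list(range(len(seqs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                if same_locus(seqs[i], seqs[j], max_offset):
                    parent[find(i)] = find(j)
        out[family] = len({find(i) for i in range(len(seqs))})
    return out


def pearson_loci(loci_a: Sequence[float], loci_b: Sequence[float],
                 ) -> tuple[float, float]:
    """Pearson correlation of two locus-count vectors over the same families.

    Returns (r, r rounded to 2 decimals).  Requires length >= 3 and
    non-degenerate variance in both vectors.
    """
    a = np.asarray(loci_a, dtype=float)
    b = np.asarray(loci_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of >= 3 families")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined: zero variance")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, round(r, 2)
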
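"""Loaders for the bundled common-bean reference tables.

The package ships four small TSV tables transcribed from a published
four-organ (leaf LL, flower FL, root RL, seedling SL) common-bean small-RNA
survey: conserved mature miRNAs, conserved mature-star miRNAs, predicted
locus counts per family for three legumes, and the isomiR variant table
(variants paired with their reference miRNAs, grouped as length /
non-conserved / conserved variants; that table is printed in the DNA
alphabet and normalized to RNA on load).  They drive the exact-recomputation
test fixtures and the worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .conserved import AnnotationHit, MatureRef
from .core_io import normalize_rna

FIXTURE_LIBRARIES = ("LL", "FL", "RL", "SL")


def _read(name: str) -> pd.DataFrame:
    with resources.files("beanmir.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"family": str})


def _hits(df: pd.DataFrame, is_star: bool) -> list[AnnotationHit]:
    hits = []
    for row in df.itertuples(index=False):
        ref = MatureRef(row.name, normalize_rna(row.sequence),
                        family=str(row.family), is_star=is_star)
        counts = {lib: int(getattr(row, lib)) for lib in FIXTURE_LIBRARIES}
        hits.append(AnnotationHit(ref, counts))
    return hits


def conserved_mature_hits() -> list[AnnotationHit]:
    """The 95 conserved mature miRNA rows (29 families) with organ counts."""
    return _hits(_read("conserved_mirnas.tsv"), is_star=False)


def conserved_star_hits() -> list[AnnotationHit]:
    """The 14 conserved mature-star miRNA rows with organ counts."""
    return _hits(_read("conserved_star_mirnas.tsv"), is_star=True)


def conserved_families() -> set[str]:
    return {h.ref.family for h in conserved_mature_hits()}


def family_loci_table() -> pd.DataFrame:
    """Predicted locus counts per miRNA family for common bean (pvu),
    soybean (gma) and barrel medic (mtr); 33 families."""
    return _read("family_loci.tsv").set_index("family")


@dataclass
class IsomirFixtureRow:
    group: str            # printed variant group: length | non_conserved | conserved
    role: str             # reference | variant
    name: str
    sequence: str         # RNA alphabet
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def isomir_fixture() -> list[IsomirFixtureRow]:
    """The 26 printed isomiR variants, each preceded by its reference row."""
    rows = []
    for row in _read("isomir_variants.tsv").itertuples(index=False):
        counts = {lib: int(getattr(row, lib)) for lib in FIXTURE_LIBRARIES}
        rows.append(IsomirFixtureRow(row.group, row.role, row.name,
                                     normalize_rna(row.sequence), counts))
    return rows


def isomir_reference_set() -> list[MatureRef]:
    """Deduplicated reference miRNAs of the isomiR table (star flags from
    the ``*`` naming convention)."""
    seen: dict[str, MatureRef] = {}
    for row in isomir_fixture():
        if row.role == "reference" and row.sequence not in seen:
            seen[row.sequence] = MatureRef(row.name, row.sequence,
                                           is_star=row.name.endswith("*"))
    return list(seen.values())
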
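"""Raw-read cleaning: 3' adapter trimming, length and quality filtering,
collapsing, and the per-library 16-30 nt length-distribution summary.

Short-insert small-RNA sequencing reads through the 3' adapter, so a read
without any adapter match is treated as uninformative and discarded.
Adapter matching is exact on a minimum adapter prefix, leftmost occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import LibrarySet, SequenceRecord, collapse_to_tags, normalize_rna

MIN_TAG_LEN, MAX_TAG_LEN = 16, 30


@dataclass
class PreprocessParams:
    adapter: str = "UCGUAUGCCGUCUUCUGCUUG"   # classic small-RNA 3' adapter
    min_len: int = MIN_TAG_LEN
    max_len: int = MAX_TAG_LEN
    min_mean_quality: float = 20.0
    adapter_min_prefix: int = 8

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter sequence must be non-empty")
        self.adapter = normalize_rna(self.adapter)
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if self.adapter_min_prefix < 6:
            raise ValueError("adapter_min_prefix must be >= 6")


def trim_adapter(read: SequenceRecord, params: PreprocessParams,
                 ) -> SequenceRecord | None:
    """Return the insert before the leftmost adapter match, or None.

    The match is exact on the first ``adapter_min_prefix`` bases of the
    adapter.  Reads with no match anywhere, and reads whose insert is empty
    (adapter at position 0), are discarded (returns None).
    """
    probe = params.adapter[: params.adapter_min_prefix]
    pos = read.sequence.find(probe)
    if pos <= 0:
        return None
    qual = read.quality[:pos] if read.quality is not None else None
    return SequenceRecord(read.id, read.sequence[:pos], qual)


def filter_reads(reads: Iterable[SequenceRecord], params: PreprocessParams,
                 ) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Length/quality filter on adapter-trimmed reads.

    Kept iff min_len <= length <= max_len and mean Phred >= threshold
    (quality test skipped when scores are absent).  The discard tally
    partitions the inputs: kept + discarded == total.
    """
    kept: list[SequenceRecord] = []
    tally = {"kept": 0, "too_short": 0, "too_long": 0, "low_quality": 0}
    for read in reads:
        n = len(read)
        if n < params.min_len:
            tally["too_short"] += 1
        elif n > params.max_len:
            tally["too_long"] += 1
        elif (read.quality is not None
              and float(np.mean(read.quality)) < params.min_mean_quality):
            tally["low_quality"] += 1
        else:
            tally["kept"] += 1
            kept.append(read)
    return kept, tally


def preprocess_library(raw_reads: Iterable[SequenceRecord],
                       params: PreprocessParams,
                       ) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Trim then filter one library; tally includes adapter discards."""
    trimmed: list[SequenceRecord] = []
    no_adapter = 0
    for read in raw_reads:
        t = trim_adapter(read, params)
        if t is None:
            no_adapter += 1
        else:
            trimmed.append(t)
    kept, tally = filter_reads(trimmed, params)
    tally["no_adapter"] = no_adapter
    return kept, tally


def preprocess_libraries(raw: Mapping[str, Iterable[SequenceRecord]],
                         params: PreprocessParams,
                         libraries: Sequence[str],
                         ) -> tuple[LibrarySet, dict[str, dict[str, int]]]:
    kept_by_lib = {}
    tallies = {}
    for lib, reads in raw.items():
        kept, tally = preprocess_library(reads, params)
        kept_by_lib[lib] = kept
        tallies[lib] = tally
    return collapse_to_tags(kept_by_lib, libraries), tallies


def length_distribution(libset: LibrarySet,
                        min_len: int = MIN_TAG_LEN,
                        max_len: int = MAX_TAG_LEN) -> pd.DataFrame:
    """Percentage of unique and redundant sequences per length per library.

    Returns a DataFrame indexed by length (min_len..max_len) with columns
    ``(library, "unique_pct")`` and ``(library, "redundant_pct")``; each
    non-empty library's two columns sum to 100.
    """
    lengths = range(min_len, max_len + 1)
    uniq = {lib: np.zeros(len(lengths)) for lib in libset.libraries}
    redun = {lib: np.zeros(len(lengths)) for lib in libset.libraries}
    for tag in libset.sorted_tags():
        n = len(tag.sequence)
        if not (min_len <= n <= max_len):
            raise ValueError(f"tag of length {n} outside [{min_len}, {max_len}]")
        i = n - min_len
        for lib, c in tag.counts.items():
            if c > 0:
                uniq[lib][i] += 1
                redun[lib][i] += c
    data = {}
    for lib in libset.libraries:
        for label, vec in (("unique_pct", uniq[lib]), ("redundant_pct", redun[lib])):
            s = vec.sum()
            data[(lib, label)] = 100.0 * vec / s if s > 0 else vec
    return pd.DataFrame(data, index=pd.Index(lengths, name="length"))
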
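"""Minimum-free-energy folding of candidate precursor windows, stem-loop
validation, and read-signature scoring of novel miRNA candidates.

The folding engine is an exact dynamic program over the simplified energy
model in :mod:`beanmir.energy`, restricted to multiloop-free structures:
any number of side-by-side external stems, each a nested chain of pairs
separated by stacks, bulges or internal loops and closed by one terminal
hairpin loop.  This is sufficient for pre-miRNA geometry, where the object
of interest is a single stem-loop carrying the miRNA/miRNA* duplex, and it
makes the optimum independently checkable by exhaustive enumeration.

Validation follows standard plant-miRNA annotation practice: the mature
sequence must sit on one arm of a stem-loop clear of the terminal loop,
be mostly paired, tolerate only small asymmetric bulges in the duplex
region, and the window must fold with a normalized free energy below a
stability threshold.  The predicted star sequence is the pairing partner
of the mature shifted to leave the 2-nt 3' overhangs that Dicer processing
produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_io import SequenceRecord, Tag, normalize_rna, revcomp
from .energy import FoldParams, can_pair

MAX_FOLD_LEN = 1000
INF = float("inf")

# validation thresholds (plant pre-miRNA annotation practice)
MIN_MATURE_PAIRED_FRAC = 0.60
MAX_DUPLEX_BULGES = 2
MAX_DUPLEX_BULGE_SIZE = 3
MAX_NORMALIZED_MFE = -0.25     # kcal/mol per nt of folded window

# novel-candidate scoring
STAR_BONUS = 2.0
INCONSISTENCY_PENALTY = 4.0
NOVEL_KEEP_THRESHOLD = 1.0
CONSISTENT_FRACTION = 0.90


@dataclass
class SecondaryStructure:
    sequence: str
    pairing: str              # dot-bracket
    mfe: float                # kcal/mol

    def partners(self) -> list[int | None]:
        return pairing_partners(self.pairing)


def pairing_partners(dotbracket: str) -> list[int | None]:
    partner: list[int | None] = [None] * len(dotbracket)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"bad dot-bracket symbol {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return partner


def fold_min_energy(sequence: str, params: FoldParams | None = None,
                    ) -> SecondaryStructure:
    """Minimum-energy multiloop-free structure by dynamic programming.

    ``V[i][j]`` is the best energy of the region closed by pair (i, j) —
    either a terminal hairpin loop or a two-loop (stack / bulge / internal
    loop, sides capped at ``params.max_loop_side``) to an inner pair.  An
    unconstrained prefix recursion then assembles external stems.  Only the
    single lowest-energy structure is returned, by construction.
    """
    params = params or FoldParams()
    s = normalize_rna(sequence)
    n = len(s)
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    minl, maxs = params.min_loop, params.max_loop_side
    pair_ok = [[can_pair(s[i], s[j]) for j in range(n)] for i in range(n)]

    V = [dict() for _ in range(n)]  # V[i][j] for pairable (i, j)

    def v(i: int, j: int) -> float:
        return V[i].get(j, INF)

    for span in range(minl + 1, n):
        for i in range(n - span):
            j = i + span
            if not pair_ok[i][j]:
                continue
            best = params.hairpin_penalty(j - i - 1)
            kmax = min(i + 1 + maxs, j - minl - 1)
            for k in range(i + 1, kmax + 1):
                lmin = max(k + minl + 1, j - 1 - maxs)
                row = V[k]
                for l in range(lmin, j):
                    e_in = row.get(l)
                    if e_in is None:
                        continue
                    n5, n3 = k - i - 1, j - l - 1
                    if n5 == 0 and n3 == 0:
                        e = e_in + params.stack_energy((s[i], s[j]), (s[k], s[l]))
                    else:
                        e = e_in + params.two_loop_energy(n5, n3)
                    if e < best:
                        best = e
            V[i][j] = best

    W = [0.0] * (n + 1)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j - minl - 1):
            e = V[i].get(j - 1)
            if e is not None:
                e += W[i]
                if e < best:
                    best = e
        W[j] = best

    # traceback
    db = ["."] * n
    eps = 1e-9

    def trace_v(i: int, j: int) -> None:
        db[i], db[j] = "(", ")"
        target = V[i][j]
        if abs(target - params.hairpin_penalty(j - i - 1)) < eps:
            return
        kmax = min(i + 1 + maxs, j - minl - 1)
        for k in range(i + 1, kmax + 1):
            lmin = max(k + minl + 1, j - 1 - maxs)
            for l in range(lmin, j):
                e_in = V[k].get(l)
                if e_in is None:
                    continue
                n5, n3 = k - i - 1, j - l - 1
                if n5 == 0 and n3 == 0:
                    e = e_in + params.stack_energy((s[i], s[j]), (s[k], s[l]))
                else:
                    e = e_in + params.two_loop_energy(n5, n3)
                if abs(e - target) < eps:
                    trace_v(k, l)
                    return
        raise AssertionError("traceback failed in V")  # pragma: no cover

    j = n
    while j > 0:
        if abs(W[j] - W[j - 1]) < eps:
            j -= 1
            continue
        found = False
        for i in range(0, j - minl - 1):
            e = V[i].get(j - 1)
            if e is not None and abs(W[i] + e - W[j]) < eps:
                trace_v(i, j - 1)
                j = i
                found = True
                break
        if not found:  # pragma: no cover
            raise AssertionError("traceback failed in W")

    mfe = W[n] if W[n] < -eps else 0.0
    return SecondaryStructure(s, "".join(db), float(mfe))


def structure_energy(sequence: str, dotbracket: str,
                     params: FoldParams | None = None) -> float:
    """Recompute the energy of a multiloop-free dot-bracket structure."""
    params = params or FoldParams()
    s = normalize_rna(sequence)
    partner = pairing_partners(dotbracket)
    for i, p in enumerate(partner):
        if p is not None and p > i and not can_pair(s[i], s[p]):
            raise ValueError(f"illegal pair {s[i]}:{s[p]} at ({i}, {p})")
    total = 0.0
    depth = 0
    for i, c in enumerate(dotbracket):
        if c == "(":
            if depth == 0:
                total += _chain_energy(s, partner, i, partner[i], params)
            depth += 1
        elif c == ")":
            depth -= 1
    return total


def _chain_energy(s: str, partner: list[int | None], i: int, j: int,
                  params: FoldParams) -> float:
    inner = [(k, partner[k]) for k in range(i + 1, j)
             if partner[k] is not None and partner[k] > k
             and _direct_child(k, partner[k], i, j, partner)]
    if len(inner) > 1:
        raise ValueError("multibranch loops are outside the energy model")
    if not inner:
        loop = j - i - 1
        if loop < params.min_loop:
            raise ValueError(f"hairpin loop of {loop} < min_loop")
        return params.hairpin_penalty(loop)
    (k, l), = inner
    n5, n3 = k - i - 1, j - l - 1
    if n5 == 0 and n3 == 0:
        e = params.stack_energy((s[i], s[j]), (s[k], s[l]))
    else:
        e = params.two_loop_energy(n5, n3)
    return e + _chain_energy(s, partner, k, l, params)


def _direct_child(k: int, l: int, i: int, j: int,
                  partner: list[int | None]) -> bool:
    for m in range(i + 1, k):
        p = partner[m]
        if p is not None and p > l:
            return False
    return True


@dataclass
class PrecursorCandidate:
    """A candidate stem-loop window around an exact mature occurrence."""

    source_id: str
    strand: str                      # "+" or "-"
    window: tuple[int, int]          # 0-based half-open, source coordinates
    window_seq: str                  # oriented 5'->3' on the given strand
    mature_pos: tuple[int, int]      # relative to window_seq
    structure: SecondaryStructure | None = None
    arm: str | None = None           # "5p" or "3p"
    star_pos: tuple[int, int] | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    verdict: bool | None = None


def find_precursor_candidates(mature: str, est_db: Sequence[SequenceRecord],
                              flank: int = 200) -> list[PrecursorCandidate]:
    """Unfolded candidate windows for every exact full-length occurrence of
    the mature sequence in the EST/GSS set, both strands.

    The arm is unknown a priori, so each occurrence yields up to three
    windows: mature-centered, mature near the window's 5' end (precursor
    extends 3'), and mature near the 3' end.  Windows are clipped at the
    sequence ends and deduplicated.
    """
    m = normalize_rna(mature)
    out: list[PrecursorCandidate] = []
    for rec in est_db:
        seq = rec.sequence
        for strand, probe in (("+", m), ("-", revcomp(m))):
            start = seq.find(probe)
            while start >= 0:
                end = start + len(probe)
                windows = {
                    (max(0, start - flank // 2), min(len(seq), end + flank // 2)),
                    (max(0, start - 10), min(len(seq), end + flank)),
                    (max(0, start - flank), min(len(seq), end + 10)),
                }
                for w0, w1 in sorted(windows):
                    wseq = seq[w0:w1]
                    if strand == "+":
                        mpos = (start - w0, end - w0)
                    else:
                        wseq = revcomp(wseq)
                        mpos = (w1 - end, w1 - start)
                    out.append(PrecursorCandidate(rec.id, strand, (w0, w1),
                                                  wseq, mpos))
                start = seq.find(probe, start + 1)
    return out


def validate_hairpin(candidate: PrecursorCandidate,
                     params: FoldParams | None = None,
                     min_paired_frac: float = MIN_MATURE_PAIRED_FRAC,
                     max_bulges: int = MAX_DUPLEX_BULGES,
                     max_bulge_size: int = MAX_DUPLEX_BULGE_SIZE,
                     max_norm_mfe: float = MAX_NORMALIZED_MFE,
                     ) -> PrecursorCandidate:
    """Fold (if needed) and validate a candidate window as a pre-miRNA.

    Criteria: (a) the mature lies entirely on one arm of a single stem-loop
    and clear of its terminal loop; (b) >= 60% of mature bases paired;
    (c) at most two asymmetric bulges of <= 3 nt inside the mature/star
    duplex; (d) normalized MFE of the window <= -0.25 kcal/mol/nt.  On a
    true verdict the star interval is predicted from the pairing partner of
    the mature, shifted to leave 2-nt 3' overhangs.
    """
    params = params or FoldParams()
    a, b = candidate.mature_pos
    wseq = candidate.window_seq
    if not (0 <= a < b <= len(wseq)):
        raise ValueError("mature_pos outside window")
    if candidate.structure is None:
        candidate.structure = fold_min_energy(wseq, params)
    partner = candidate.structure.partners()

    mature_partners = [(i, partner[i]) for i in range(a, b) if partner[i] is not None]
    paired_frac = len(mature_partners) / (b - a)
    flags = {"mature_paired": paired_frac >= min_paired_frac}

    if mature_partners:
        ps = [p for _, p in mature_partners]
        all_down = all(p >= b for p in ps)
        all_up = all(p < a for p in ps)
        flags["single_arm"] = all_down or all_up
        candidate.arm = "5p" if all_down else ("3p" if all_up else None)
    else:
        flags["single_arm"] = False

    # terminal loop of the mature's stem: follow the nested chain inward
    # from the innermost mature pair and check the mature stays outside it
    flags["clear_of_loop"] = False
    if flags["single_arm"]:
        i0, j0 = max(((min(i, p), max(i, p)) for i, p in mature_partners),
                     key=lambda ij: ij[0])
        while True:
            inner = [k for k in range(i0 + 1, j0)
                     if partner[k] is not None and i0 < partner[k] < j0
                     and partner[k] > k]
            if not inner:
                break
            k = min(inner)
            i0, j0 = k, partner[k]
        flags["clear_of_loop"] = not (max(a, i0 + 1) < min(b, j0))

    # asymmetric bulges within the duplex region spanned by the mature
    n_bulges, oversized = 0, False
    for (u, pu), (v, pv) in zip(mature_partners, mature_partners[1:]):
        g_m = v - u - 1
        g_s = abs(pu - pv) - 1
        if g_m != g_s:
            n_bulges += 1
            if max(g_m, g_s) > max_bulge_size:
                oversized = True
    flags["duplex_bulges"] = n_bulges <= max_bulges and not oversized

    norm = candidate.structure.mfe / len(wseq)
    flags["stability"] = norm <= max_norm_mfe

    candidate.flags = flags
    candidate.verdict = all(flags.values())

    if candidate.verdict and mature_partners:
        last_paired, p_last = mature_partners[-1]
        delta = (b - 1) - last_paired
        star_start = p_last + delta + 2
        star_end = star_start + (b - a)
        candidate.star_pos = (max(0, star_start), min(len(wseq), star_end))
    return candidate


@dataclass
class NovelCandidate:
    """A validated precursor scored from the read signature in its window."""

    precursor: PrecursorCandidate
    mature_reads: int
    star_reads: int
    loop_reads: int
    inconsistent_reads: int
    score: float

    @property
    def total_reads(self) -> int:
        return (self.mature_reads + self.star_reads
                + self.loop_reads + self.inconsistent_reads)


def score_novel(candidate: PrecursorCandidate, tags: Iterable[Tag],
                star_bonus: float = STAR_BONUS,
                inconsistency_penalty: float = INCONSISTENCY_PENALTY,
                consistent_frac: float = CONSISTENT_FRACTION,
                ) -> NovelCandidate | None:
    """Partition window-mapped reads into mature/star/loop/inconsistent bins
    and score the candidate.

    A read is consistent when >= 90% of its positions fall in one bin; star
    evidence adds a fixed bonus, and diffuse (siRNA- or degradation-like)
    signatures are penalized by the inconsistent fraction.  Candidates with
    no mapped reads are dropped (returns None).
    """
    if not candidate.verdict:
        raise ValueError("score_novel requires a validated candidate")
    a, b = candidate.mature_pos
    star = candidate.star_pos or (0, 0)
    lo, hi = (b, star[0]) if star[0] >= b else (star[1], a)
    regions = {"mature": range(a, b), "star": range(*star), "loop": range(lo, hi)}

    bins = {"mature": 0, "star": 0, "loop": 0, "inconsistent": 0}
    wseq = candidate.window_seq
    for tag in tags:
        pos = wseq.find(tag.sequence)
        if pos < 0:
            continue
        span = range(pos, pos + len(tag.sequence))
        n = len(span)
        assigned = "inconsistent"
        for label, region in regions.items():
            overlap = max(0, min(span.stop, region.stop) - max(span.start, region.start))
            if overlap / n >= consistent_frac:
                assigned = label
                break
        bins[assigned] += tag.total()

    total = sum(bins.values())
    if total == 0:
        return None
    score = (math.log1p(bins["mature"])
             + (star_bonus if bins["star"] > 0 else 0.0)
             - inconsistency_penalty * bins["inconsistent"] / total)
    return NovelCandidate(candidate, bins["mature"], bins["star"],
                          bins["loop"], bins["inconsistent"], score)


def dinucleotide_shuffle(sequence: str, rng) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian walk on the
    first-order transition multigraph)."""
    s = normalize_rna(sequence)
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for x, y in zip(s, s[1:]):
        edges.setdefault(x, []).append(y)
    last = s[-1]
    for _ in range(1000):
        trial = {v: list(outs) for v, outs in edges.items()}
        for outs in trial.values():
            rng.shuffle(outs)
        # walk greedily; a failed walk (stranded early) is rejected
        walk = [s[0]]
        v = s[0]
        steps = len(s) - 1
        ok = True
        for _ in range(steps):
            outs = trial.get(v)
            if not outs:
                ok = False
                break
            v = outs.pop()
            walk.append(v)
        if ok and walk[-1] == last:
            return "".join(walk)
    return s  # pathological composition; give back the input
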
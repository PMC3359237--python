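"""miRNA target prediction by intermolecular duplex free-energy minimization.

The duplex model considers only intermolecular pairing: Watson-Crick and
G:U stacks from the packaged energy table, per-nucleotide penalties for
internal mismatches and for bulges of at most 3 nt, and free (unpenalized)
unpaired ends.  A site passes when its hybrid energy reaches a configurable
fraction of the energy of the same miRNA bound to its exact reverse
complement — a ratio rule, since absolute hybrid energies vary with miRNA
length and GC content.  Pairing diagrams use ``|`` for Watson-Crick pairs,
``x`` for G:U wobbles (never counted as mismatches) and ``*`` for
mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import SequenceRecord, normalize_rna, revcomp
from .energy import FoldParams, can_pair, is_wobble

INF = float("inf")
DEFAULT_THRESHOLD_RATIO = 0.7
TAS3_THRESHOLD_RATIO = 0.55
MAX_DUPLEX_BULGE = 3

_PAIR, _MISM, _GAP_T, _GAP_M = 0, 1, 2, 3


@dataclass
class DuplexHybrid:
    """An intermolecular miRNA:target hybrid."""

    mirna: str
    target_id: str
    site: tuple[int, int]        # 0-based half-open on the target
    mfe: float                   # kcal/mol, <= 0
    diagram: str                 # one symbol per alignment column
    mirna_line: str              # miRNA 5'->3', gaps as '-'
    target_line: str             # target 3'->5', gaps as '-'


@dataclass
class TargetCall:
    hybrid: DuplexHybrid
    threshold_ratio: float
    perfect_mfe: float
    passed: bool


def _duplex_dp(m: str, r: str, params: FoldParams):
    """Min-energy local duplex of miRNA ``m`` vs reversed target ``r``.

    States per cell: ends-in-pair, ends-in-mismatch, ends-in-target-bulge,
    ends-in-miRNA-bulge; bulges are <= 3 nt and flanked by pairs; unpaired
    ends are free.  Returns (best energy, end cell, parent map).
    """
    M, N = len(m), len(r)
    mm, bg = params.duplex_mismatch, params.duplex_bulge_nt
    D = [[[INF] * 4 for _ in range(N + 1)] for _ in range(M + 1)]
    parent: dict[tuple[int, int, int], tuple[int, int, int] | None] = {}
    best, best_cell = 0.0, None
    for i in range(1, M + 1):
        row, prev = D[i], D[i - 1]
        for j in range(1, N + 1):
            if can_pair(m[i - 1], r[j - 1]):
                # open a new helix (leading ends free) or extend
                cands: list[tuple[float, tuple[int, int, int] | None]] = [(0.0, None)]
                p = prev[j - 1]
                if p[_PAIR] < INF:
                    stack = params.stack_energy((m[i - 2], r[j - 2]),
                                                (m[i - 1], r[j - 1]))
                    cands.append((p[_PAIR] + stack, (i - 1, j - 1, _PAIR)))
                for st in (_MISM, _GAP_T, _GAP_M):
                    if p[st] < INF:
                        cands.append((p[st], (i - 1, j - 1, st)))
                e, par = min(cands, key=lambda c: c[0])
                row[j][_PAIR] = e
                parent[(i, j, _PAIR)] = par
                if e < best:
                    best, best_cell = e, (i, j, _PAIR)
            # mismatch: both strands consumed, only after pair or mismatch
            p = prev[j - 1]
            e, par = INF, None
            for st in (_PAIR, _MISM):
                if p[st] + mm < e:
                    e, par = p[st] + mm, (i - 1, j - 1, st)
            if e < INF:
                row[j][_MISM] = e
                parent[(i, j, _MISM)] = par
            # bulges: 1..3 unpaired nt on one strand, opened from a pair
            e, par = INF, None
            for k in range(1, MAX_DUPLEX_BULGE + 1):
                if j - k >= 1 and D[i][j - k][_PAIR] + bg * k < e:
                    e, par = D[i][j - k][_PAIR] + bg * k, (i, j - k, _PAIR)
            if e < INF:
                row[j][_GAP_T] = e
                parent[(i, j, _GAP_T)] = par
            e, par = INF, None
            for k in range(1, MAX_DUPLEX_BULGE + 1):
                if i - k >= 1 and D[i - k][j][_PAIR] + bg * k < e:
                    e, par = D[i - k][j][_PAIR] + bg * k, (i - k, j, _PAIR)
            if e < INF:
                row[j][_GAP_M] = e
                parent[(i, j, _GAP_M)] = par
    return best, best_cell, parent


def duplex_mfe(mirna: str, target_window: str,
               params: FoldParams | None = None,
               target_id: str = "") -> DuplexHybrid:
    """Minimum-energy intermolecular hybrid of a miRNA against a target
    window (no intramolecular pairing).  Empty inputs are an error."""
    params = params or FoldParams()
    m = normalize_rna(mirna)
    t = normalize_rna(target_window)
    r = t[::-1]  # target read 3'->5' so both indices ascend
    best, cell, parent = _duplex_dp(m, r, params)
    if cell is None:
        return DuplexHybrid(m, target_id, (0, 0), 0.0, "", "", "")
    # traceback
    cols: list[tuple[str, str, str]] = []
    cur: tuple[int, int, int] | None = cell
    end_i, end_j = cell[0], cell[1]
    start_i = start_j = None
    while cur is not None:
        i, j, st = cur
        par = parent[(i, j, st)]
        if st == _PAIR:
            sym = "x" if is_wobble(m[i - 1], r[j - 1]) else "|"
            cols.append((m[i - 1], sym, r[j - 1]))
        elif st == _MISM:
            cols.append((m[i - 1], "*", r[j - 1]))
        elif st == _GAP_T:
            pi, pj, _ = par
            for jj in range(j, pj, -1):
                cols.append(("-", " ", r[jj - 1]))
        else:  # _GAP_M
            pi, pj, _ = par
            for ii in range(i, pi, -1):
                cols.append((m[ii - 1], " ", "-"))
        start_i, start_j = i, j
        cur = par
    cols.reverse()
    mline = "".join(c[0] for c in cols)
    diagram = "".join(c[1] for c in cols)
    tline = "".join(c[2] for c in cols)
    # aligned target region in original orientation
    N = len(t)
    site = (N - end_j, N - start_j + 1)
    return DuplexHybrid(m, target_id, site, best, diagram, mline, tline)


def perfect_duplex_mfe(mirna: str, params: FoldParams | None = None) -> float:
    """Energy of the miRNA bound to its exact reverse complement."""
    return duplex_mfe(mirna, revcomp(mirna), params).mfe


def _best_site(m: str, est_seq: str, params: FoldParams,
               window: int | None = None, step: int | None = None,
               est_id: str = "") -> DuplexHybrid:
    window = window or len(m) + 14
    step = step or max(1, len(m) // 2)
    best: DuplexHybrid | None = None
    n = len(est_seq)
    starts = list(range(0, max(1, n - window + 1), step))
    if starts[-1] + window < n:
        starts.append(n - window)
    for s in starts:
        hyb = duplex_mfe(m, est_seq[s: s + window], params, est_id)
        if hyb.mfe < (best.mfe if best else 0.0):
            hyb.site = (hyb.site[0] + s, hyb.site[1] + s)
            best = hyb
    return best or DuplexHybrid(m, est_id, (0, 0), 0.0, "", "", "")


def scan_targets(mirnas: Sequence[tuple[str, str]] | dict,
                 est_db: Sequence[SequenceRecord],
                 threshold_ratio: float = DEFAULT_THRESHOLD_RATIO,
                 params: FoldParams | None = None) -> list[TargetCall]:
    """Best-site hybrids for each miRNA x EST; calls pass when the hybrid
    reaches ``threshold_ratio`` of the perfect-complement energy.

    Output is sorted by hybrid energy and independent of EST file order.
    """
    params = params or FoldParams()
    if isinstance(mirnas, dict):
        mirnas = list(mirnas.items())
    calls: list[TargetCall] = []
    for name, seq in mirnas:
        m = normalize_rna(seq)
        perfect = perfect_duplex_mfe(m, params)
        for rec in est_db:
            hyb = _best_site(m, rec.sequence, params, est_id=rec.id)
            if hyb.mfe >= 0.0:
                continue
            passed = hyb.mfe <= threshold_ratio * perfect
            hyb.mirna = name or m
            if passed:
                calls.append(TargetCall(hyb, threshold_ratio, perfect, True))
    calls.sort(key=lambda c: (c.hybrid.mfe, c.hybrid.target_id,
                              c.hybrid.site, c.hybrid.mirna))
    return calls


@dataclass
class Tas3Candidate:
    target_id: str
    site1: tuple[int, int]
    site2: tuple[int, int]
    mfe1: float
    mfe2: float
    spacing: int                 # nt between the end of site1 and start of site2


def scan_tas3(mir390: str, est_db: Sequence[SequenceRecord],
              threshold_ratio: float = TAS3_THRESHOLD_RATIO,
              params: FoldParams | None = None) -> list[Tas3Candidate]:
    """TAS3-like transcripts: ESTs with two non-overlapping miR390 hybrid
    sites at a relaxed energy ratio, reported with inter-site spacing."""
    params = params or FoldParams()
    m = normalize_rna(mir390)
    perfect = perfect_duplex_mfe(m, params)
    cutoff = threshold_ratio * perfect
    window = len(m) + 14
    out: list[Tas3Candidate] = []
    for rec in est_db:
        n = len(rec.sequence)
        sites: list[tuple[float, tuple[int, int]]] = []
        step = max(1, len(m) // 3)
        for s in range(0, max(1, n - window + 1), step):
            hyb = duplex_mfe(m, rec.sequence[s: s + window], params, rec.id)
            if hyb.mfe <= cutoff:
                sites.append((hyb.mfe, (hyb.site[0] + s, hyb.site[1] + s)))
        if len(sites) < 2:
            continue
        sites.sort(key=lambda x: (x[0], x[1]))
        # best non-overlapping pair (windows overlapping a better site are
        # duplicates of it and are collapsed away)
        best_pair = None
        for a in range(len(sites)):
            for b in range(a + 1, len(sites)):
                s1, s2 = sorted([sites[a][1], sites[b][1]])
                if s1[1] <= s2[0]:
                    cand = (sites[a][0] + sites[b][0], s1, s2,
                            sites[a][0], sites[b][0])
                    if best_pair is None or cand[0] < best_pair[0]:
                        best_pair = cand
        if best_pair is not None:
            _, s1, s2, e1, e2 = best_pair
            out.append(Tas3Candidate(rec.id, s1, s2, min(e1, e2), max(e1, e2),
                                     s2[0] - s1[1]))
    return out
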
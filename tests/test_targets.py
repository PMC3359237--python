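"""Duplex hybridization DP vs enumeration, diagram semantics, target
scanning and the dual-site TAS3 scan."""

import numpy as np
import pytest

from beanmir.core_io import SequenceRecord, revcomp
from beanmir.energy import FoldParams, can_pair
from beanmir.hairpin import dinucleotide_shuffle
from beanmir.targets import (duplex_mfe, perfect_duplex_mfe, scan_targets,
                             scan_tas3)

P = FoldParams()
WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def enum_duplex_min(m: str, t: str) -> float:
    """Independent oracle: exhaustively enumerate every pair chain allowed
    by the duplex grammar (equal-length mismatch runs or single-sided
    bulges of <= 3 nt between consecutive pairs; free unpaired ends)."""
    r = t[::-1]
    M, N = len(m), len(r)
    best = [0.0]

    def extend(i, j, energy):
        best[0] = min(best[0], energy)
        for ni in range(i + 1, M + 1):
            for nj in range(j + 1, N + 1):
                if not can_pair(m[ni - 1], r[nj - 1]):
                    continue
                di, dj = ni - i - 1, nj - j - 1
                if di == 0 and dj == 0:
                    cost = P.stack_energy((m[i - 1], r[j - 1]),
                                          (m[ni - 1], r[nj - 1]))
                elif di == dj:
                    cost = P.duplex_mismatch * di
                elif di == 0 and 1 <= dj <= 3:
                    cost = P.duplex_bulge_nt * dj
                elif dj == 0 and 1 <= di <= 3:
                    cost = P.duplex_bulge_nt * di
                else:
                    continue
                extend(ni, nj, energy + cost)

    for i in range(1, M + 1):
        for j in range(1, N + 1):
            if can_pair(m[i - 1], r[j - 1]):
                extend(i, j, 0.0)
    return best[0]


def test_perfect_complement_closed_form():
    """miRNA vs exact reverse complement: all positions pair Watson-Crick
    and the energy is the sum of the consecutive stack terms."""
    m = "UUCCACAGCUUUCUUGAACUG"
    hyb = duplex_mfe(m, revcomp(m), P)
    expected = sum(P.stack_energy((m[i], WC[m[i]]), (m[i + 1], WC[m[i + 1]]))
                   for i in range(len(m) - 1))
    assert hyb.mfe == pytest.approx(expected)
    assert hyb.diagram == "|" * len(m)
    assert hyb.site == (0, len(m))


def test_central_substitution_raises_energy_strictly():
    m = "UUCCACAGCUUUCUUGAACUG"
    t = list(revcomp(m))
    mid = len(t) // 2
    t[mid] = {"A": "C", "C": "A", "G": "A", "U": "C"}[t[mid]]
    worse = duplex_mfe(m, "".join(t), P)
    assert worse.mfe > duplex_mfe(m, revcomp(m), P).mfe


def test_wobbles_marked_x_and_not_counted_as_mismatches():
    m = "CCAUGGAACCAUGGAACCAUG"
    site = list(revcomp(m))
    wob = [i for i, b in enumerate(site) if b in "CA"][:2]
    for i in wob:
        site[i] = "U" if site[i] == "C" else "G"
    hyb = duplex_mfe(m, "".join(site), P)
    assert hyb.diagram.count("x") == 2
    assert hyb.diagram.count("*") == 0


def test_duplex_matches_enumeration_oracle():
    """DP equals exhaustive alignment enumeration on 210 random miRNA/window
    pairs of 6-12 nt each."""
    rng = np.random.default_rng(4242)
    for _ in range(210):
        m = "".join(rng.choice(list("ACGU"), int(rng.integers(6, 13))))
        t = "".join(rng.choice(list("ACGU"), int(rng.integers(6, 13))))
        assert duplex_mfe(m, t, P).mfe == pytest.approx(enum_duplex_min(m, t),
                                                        abs=1e-6), (m, t)


def test_perfect_complement_is_optimal_among_equal_length_windows():
    rng = np.random.default_rng(7)
    m = "".join(rng.choice(list("ACGU"), 21))
    opt = duplex_mfe(m, revcomp(m), P).mfe
    for _ in range(25):
        w = "".join(rng.choice(list("ACGU"), 21))
        assert opt <= duplex_mfe(m, w, P).mfe + 1e-9


def test_diagram_symbols_match_energy_decomposition():
    m = "GGCAUCGGGAGCGUAACGCCC"
    t = list(revcomp(m))
    t[10] = {"A": "C", "C": "A", "G": "A", "U": "C"}[t[10]]
    hyb = duplex_mfe(m, "".join(t), P)
    assert hyb.mfe <= 0
    assert len(hyb.diagram) == len(hyb.mirna_line) == len(hyb.target_line)
    # every * contributes exactly one mismatch penalty; recompute
    n_star = hyb.diagram.count("*")
    pairs = [i for i, c in enumerate(hyb.diagram) if c in "|x"]
    e = n_star * P.duplex_mismatch
    for a, b in zip(pairs, pairs[1:]):
        if b == a + 1:
            e += P.stack_energy((hyb.mirna_line[a], hyb.target_line[a]),
                                (hyb.mirna_line[b], hyb.target_line[b]))
    gaps = hyb.diagram.count(" ")
    e += gaps * P.duplex_bulge_nt
    assert e == pytest.approx(hyb.mfe, abs=1e-6)


def test_empty_duplex_input_is_an_error():
    with pytest.raises(ValueError):
        duplex_mfe("", "ACGU", P)


def test_scan_recovers_planted_sites(small_sim):
    refsets, _, _ = small_sim
    truth = refsets.truth
    genes = {g.name: g for g in truth.genes}
    mirnas = [(name, genes[name].mature) for name, *_ in truth.target_sites]
    calls = scan_targets(mirnas, refsets.ests, params=P)
    passed = {(c.hybrid.mirna, c.hybrid.target_id) for c in calls}
    hits = sum(1 for name, est, *_ in truth.target_sites
               if (name, est) in passed)
    assert hits / len(truth.target_sites) >= 0.9
    # wobbled planted sites still pass and show x symbols
    for c in calls:
        wob = next((w for n, e, s0, s1, w in truth.target_sites
                    if (n, e) == (c.hybrid.mirna, c.hybrid.target_id)), None)
        if wob:
            assert c.hybrid.diagram.count("x") >= wob


def test_scan_output_independent_of_est_order(small_sim):
    refsets, _, _ = small_sim
    gene = refsets.truth.genes[0]
    mirnas = [(gene.name, gene.mature)]
    fwd = scan_targets(mirnas, refsets.ests, params=P)
    rev = scan_targets(mirnas, list(reversed(refsets.ests)), params=P)
    assert [(c.hybrid.target_id, c.hybrid.site, c.hybrid.mfe) for c in fwd] == \
        [(c.hybrid.target_id, c.hybrid.site, c.hybrid.mfe) for c in rev]


def test_shuffled_ests_rarely_pass(small_sim, rng):
    """Null scan: against dinucleotide-shuffled ESTs the pass rate at the
    default ratio is below 1%."""
    refsets, _, _ = small_sim
    truth = refsets.truth
    genes = {g.name: g for g in truth.genes}
    mirnas = [(n, genes[n].mature) for n, *_ in truth.target_sites[:5]]
    shuffled = [SequenceRecord(r.id, dinucleotide_shuffle(r.sequence, rng))
                for r in refsets.ests]
    calls = scan_targets(mirnas, shuffled, params=P)
    n_pairs = len(mirnas) * len(shuffled)
    assert len(calls) / n_pairs < 0.01


def test_tas3_dual_site_detection(rng):
    mir390 = "AAGCUCAGGAGGGAUAGCGCC"
    site = revcomp(mir390)
    spacer = "".join(rng.choice(list("ACGU"), 150))
    flank = "".join(rng.choice(list("ACGU"), 60))
    est_two = SequenceRecord("tas", flank + site + spacer + site + flank)
    est_one = SequenceRecord("single", flank + site + flank)
    cands = scan_tas3(mir390, [est_two, est_one], params=P)
    assert [c.target_id for c in cands] == ["tas"]
    c = cands[0]
    assert c.spacing == 150
    assert c.site1 == (60, 81) and c.site2 == (81 + 150, 81 + 150 + 21)
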
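"""Folding DP vs exhaustive enumeration, structure-energy consistency,
precursor validation, star prediction and novel scoring."""

from functools import lru_cache

import numpy as np
import pytest

from beanmir.core_io import SequenceRecord, Tag, revcomp
from beanmir.energy import FoldParams, can_pair
from beanmir.hairpin import (PrecursorCandidate, dinucleotide_shuffle,
                             find_precursor_candidates, fold_min_energy,
                             score_novel, structure_energy, validate_hairpin)

P = FoldParams()


def enum_fold_min(s: str) -> float:
    """Independent oracle: exhaustively enumerate every multiloop-free
    structure under the same grammar (hairpin loops >= min_loop, two-loop
    sides <= max_loop_side, any number of external stems) and take the
    minimum energy, computed directly from the loop decomposition."""
    n = len(s)
    minl, maxs = P.min_loop, P.max_loop_side

    @lru_cache(maxsize=None)
    def closed(i, j):
        out = []
        if j - i - 1 >= minl:
            out.append(P.hairpin_penalty(j - i - 1))
        for k in range(i + 1, min(i + 1 + maxs, j)):
            for l in range(max(k + minl + 1, j - 1 - maxs), j):
                if l <= k or not can_pair(s[k], s[l]):
                    continue
                n5, n3 = k - i - 1, j - l - 1
                cost = (P.stack_energy((s[i], s[j]), (s[k], s[l]))
                        if n5 == 0 and n3 == 0 else P.two_loop_energy(n5, n3))
                out.extend(cost + e for e in closed(k, l))
        return tuple(out)

    @lru_cache(maxsize=None)
    def ext(i):
        if i >= n:
            return (0.0,)
        res = list(ext(i + 1))
        for k in range(i + minl + 1, n):
            if can_pair(s[i], s[k]):
                for e1 in closed(i, k):
                    for e2 in ext(k + 1):
                        res.append(e1 + e2)
        return tuple(res)

    m = min(ext(0))
    return m if m < -1e-9 else 0.0


def test_fold_unpairable_sequence_is_open():
    s = fold_min_energy("AAAAAAAAAA", P)
    assert s.pairing == "." * 10 and s.mfe == 0.0


def test_fold_gc_stem_closed_form():
    """GGGGAAAACCCC folds into a 4-pair GC stem on a tetraloop whose energy
    is three GG/CC stacks plus the 4-nt hairpin penalty."""
    s = fold_min_energy("GGGGAAAACCCC", P)
    assert s.pairing == "((((....))))"
    expected = 3 * P.stack_energy(("G", "C"), ("G", "C")) + P.hairpin_penalty(4)
    assert s.mfe == pytest.approx(expected)


def test_fold_invariant_under_dna_aliasing():
    rna = fold_min_energy("GGGCGUAAUCGCCC", P)
    dna = fold_min_energy("gggcgtaatcgccc", P)
    assert (rna.pairing, rna.mfe) == (dna.pairing, dna.mfe)


def test_fold_rejects_bad_symbols_and_overlong_input():
    with pytest.raises(ValueError):
        fold_min_energy("ACGN", P)
    with pytest.raises(ValueError):
        fold_min_energy("A" * 1001, P)


def test_fold_matches_enumeration_oracle_on_random_sequences():
    """DP optimum equals exhaustive enumeration on 210 random sequences of
    8-20 nt, and the energy recomputed from the emitted dot-bracket equals
    the reported MFE."""
    rng = np.random.default_rng(42)
    for case in range(210):
        n = int(rng.integers(8, 17)) if case < 170 else int(rng.integers(17, 21))
        s = "".join(rng.choice(list("ACGU"), n))
        folded = fold_min_energy(s, P)
        assert folded.mfe == pytest.approx(enum_fold_min(s), abs=1e-6), s
        if folded.mfe < 0:
            assert structure_energy(s, folded.pairing, P) == \
                pytest.approx(folded.mfe, abs=1e-6)


def test_structure_energy_accepts_external_stems_rejects_multibranch():
    # two side-by-side external stems are inside the model ...
    e = structure_energy("GGGAAAACCCGGGAAAACCCAAA",
                         "(((....)))(((....)))...", P)
    assert e < 0
    # ... but two stems under one closing pair (a multiloop) are not
    with pytest.raises(ValueError):
        structure_energy("GGGGAAAACCCGGGAAAACCCC",
                         "((((....)))(((....))))", P)


def test_planted_precursors_validate(small_sim):
    """Generator-validator closure: every planted precursor EST yields a
    window that folds into a validated stem-loop."""
    refsets, _, _ = small_sim
    ests = {r.id: r for r in refsets.ests}
    for gene in refsets.truth.genes:
        cands = find_precursor_candidates(gene.mature, [ests[gene.est_id]])
        assert cands, gene.name
        assert any(validate_hairpin(c, P).verdict for c in cands), gene.name


def test_mature_across_terminal_loop_fails(small_sim):
    refsets, _, _ = small_sim
    gene = refsets.truth.genes[0]
    est = next(r for r in refsets.ests if r.id == gene.est_id)
    cand = next(c for c in find_precursor_candidates(gene.mature, [est])
                if validate_hairpin(c, P).verdict)
    # move the "mature" onto the loop: spans the hairpin loop center
    n = len(cand.window_seq)
    mid = (cand.mature_pos[0] + (cand.star_pos[0] if cand.star_pos else n)) // 2
    bad = PrecursorCandidate(cand.source_id, cand.strand, cand.window,
                             cand.window_seq, (mid, min(mid + 21, n)),
                             structure=cand.structure)
    validate_hairpin(bad, P)
    assert not bad.verdict and not bad.flags["clear_of_loop"]


def test_mature_pos_outside_window_is_an_error():
    cand = PrecursorCandidate("x", "+", (0, 12), "GGGGAAAACCCC", (5, 30))
    with pytest.raises(ValueError):
        validate_hairpin(cand, P)


def test_shuffled_windows_fail_validation(small_sim, rng):
    """Dinucleotide-shuffled precursor windows lose the planted duplex and
    fail validation at least 95% of the time (stability and geometry)."""
    refsets, _, _ = small_sim
    ests = {r.id: r for r in refsets.ests}
    genes = refsets.truth.genes[:2]
    n_total = n_fail = 0
    for gene in genes:
        cand = next(c for c in
                    find_precursor_candidates(gene.mature, [ests[gene.est_id]])
                    if validate_hairpin(c, P).verdict)
        for _ in range(20):
            shuf = dinucleotide_shuffle(cand.window_seq, rng)
            sc = PrecursorCandidate(cand.source_id, cand.strand, cand.window,
                                    shuf, cand.mature_pos)
            try:
                validate_hairpin(sc, P)
                ok = bool(sc.verdict)
            except ValueError:
                ok = False
            n_total += 1
            n_fail += not ok
    assert n_fail / n_total >= 0.95


def test_dinucleotide_shuffle_preserves_composition(rng):
    s = "GGGCGUAAUCGCCCAUGCUAGGCAUCG"
    t = dinucleotide_shuffle(s, rng)
    def dinucs(x):
        from collections import Counter
        return Counter(zip(x, x[1:]))
    assert dinucs(t) == dinucs(s) and t[0] == s[0] and t[-1] == s[-1]


def test_star_prediction_is_an_involution(small_sim):
    """Treating the predicted star as the mature predicts the original
    mature interval back (2-nt 3' overhang convention on both strands)."""
    refsets, _, _ = small_sim
    ests = {r.id: r for r in refsets.ests}
    checked = 0
    for gene in refsets.truth.genes[:4]:
        cand = next(c for c in
                    find_precursor_candidates(gene.mature, [ests[gene.est_id]])
                    if validate_hairpin(c, P).verdict)
        back = PrecursorCandidate(cand.source_id, cand.strand, cand.window,
                                  cand.window_seq, cand.star_pos,
                                  structure=cand.structure)
        validate_hairpin(back, P)
        if back.verdict:
            assert back.star_pos == cand.mature_pos
            checked += 1
    assert checked >= 2


def _validated_candidate(small_sim):
    refsets, _, _ = small_sim
    gene = refsets.truth.genes[0]
    est = next(r for r in refsets.ests if r.id == gene.est_id)
    cand = next(c for c in find_precursor_candidates(gene.mature, [est])
                if validate_hairpin(c, FoldParams()).verdict)
    return cand, gene


def test_star_reads_raise_score_strictly(small_sim):
    cand, gene = _validated_candidate(small_sim)
    a, b = cand.mature_pos
    mature_tag = Tag(cand.window_seq[a:b], {"LL": 50})
    star_tag = Tag(cand.window_seq[slice(*cand.star_pos)], {"LL": 5})
    without = score_novel(cand, [mature_tag])
    with_star = score_novel(cand, [mature_tag, star_tag])
    assert with_star.score > without.score
    assert with_star.star_reads == 5


def test_diffuse_read_signature_is_penalized(small_sim):
    cand, _ = _validated_candidate(small_sim)
    w = cand.window_seq
    a, b = cand.mature_pos
    diffuse = [Tag(w[i:i + 20], {"LL": 10})
               for i in range(0, len(w) - 20, 4)]
    scored = score_novel(cand, diffuse)
    clean = score_novel(cand, [Tag(w[a:b], {"LL": 100})])
    assert scored.inconsistent_reads > 0
    assert scored.score < clean.score


def test_no_mapped_reads_drops_candidate(small_sim):
    cand, _ = _validated_candidate(small_sim)
    assert score_novel(cand, [Tag("A" * 25, {"LL": 3})]) is None


def test_minus_strand_occurrence_reported(small_sim):
    refsets, _, _ = small_sim
    gene = refsets.truth.genes[0]
    flipped = SequenceRecord("flip", revcomp(
        next(r for r in refsets.ests if r.id == gene.est_id).sequence))
    cands = find_precursor_candidates(gene.mature, [flipped])
    assert cands and all(c.strand == "-" for c in cands)
    for c in cands:
        a, b = c.mature_pos
        assert c.window_seq[a:b] == gene.mature


def test_single_mismatch_occurrence_is_not_a_candidate():
    mature = "GGCAUCGGGAGCGUAACGCCC"
    est = SequenceRecord("e", "AAAA" + mature[:-1] + "A" + "UUUU")
    assert find_precursor_candidates(mature, [est]) == []
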
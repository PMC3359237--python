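"""Family pooling, size factors, variance stabilization and clustering."""

import numpy as np
import pandas as pd
import pytest

from beanmir import fixtures
from beanmir.expression import (fit_common_dispersion, first_merge_pair, hca,
                                linkage_to_newick, pool_families, size_factors,
                                vst)


def test_pool_families_hand_sum(fixture_run):
    """miR157 pools its two member miRNAs: LL = 3114 + 361 = 3475."""
    k = fixture_run["family_counts"]
    assert k.loc["157", "LL"] == 3475
    assert k.loc["157", "FL"] == 2787 + 30


def test_single_member_family_row_equals_member_counts(fixture_run):
    k = fixture_run["family_counts"]
    assert list(k.loc["1511"]) == [978, 625, 449, 1529]


def test_star_sequences_excluded_from_pooling(fixture_run):
    """The miR166 row ignores the five star entries (70860 reads in LL alone
    would otherwise dominate)."""
    k = fixture_run["family_counts"]
    mature_ll = sum(h.counts["LL"] for h in fixtures.conserved_mature_hits()
                    if h.ref.family == "166")
    assert k.loc["166", "LL"] == mature_ll


def test_promoted_families_join_the_matrix(fixture_run):
    k = fixture_run["family_counts"]
    assert k.shape == (33, 4)
    assert {"1510", "2199", "4376", "479"} <= set(k.index)
    # 1510 row sums its two retained variants
    assert k.loc["1510", "LL"] == 463 + 3313


def test_size_factors_toy_matrix():
    """[[2,8],[4,16],[6,24]]: geometric means (4,8,12); all ratios are
    (1/2, 2), so s = (1/2, 2)."""
    k = pd.DataFrame([[2, 8], [4, 16], [6, 24]], columns=["a", "b"])
    s = size_factors(k)
    assert s["a"] == pytest.approx(0.5)
    assert s["b"] == pytest.approx(2.0)


def test_size_factors_identical_columns_are_one():
    k = pd.DataFrame({"a": [3, 10, 7], "b": [3, 10, 7]})
    assert size_factors(k).to_numpy() == pytest.approx([1.0, 1.0])


def test_size_factors_scale_equivariance(fixture_run):
    """A duplicated-then-doubled column gets exactly twice the factor of its
    twin, and scaling a column by c scales its factor by c relative to every
    other column (the estimator is defined up to a common rescaling)."""
    k = fixture_run["family_counts"]
    k_dup = k.copy()
    k_dup["RL2"] = k_dup["RL"] * 2
    s_dup = size_factors(k_dup)
    assert s_dup["RL2"] == pytest.approx(2 * s_dup["RL"])

    s = size_factors(k)
    k2 = k.copy()
    k2["RL"] = k2["RL"] * 3
    s2 = size_factors(k2)
    assert s2["RL"] / s2["LL"] == pytest.approx(3 * s["RL"] / s["LL"])


def test_size_factors_need_an_all_positive_row():
    k = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError):
        size_factors(k)


def test_vst_zero_dispersion_is_two_sqrt():
    k = pd.DataFrame({"a": [1, 4, 9], "b": [1, 4, 9]})
    res = vst(k, dispersion=0.0)
    assert res.t.to_numpy() == pytest.approx(2 * np.sqrt(k.to_numpy()))


def test_vst_monotone_in_counts(fixture_run):
    k = fixture_run["family_counts"]
    res = vst(k)
    k2 = k.copy()
    k2.iloc[0, 0] += 100
    res2 = vst(k2, s=None, dispersion=res.dispersion)
    # recompute with the same size factors to isolate monotonicity
    from beanmir.expression import size_factors as sf
    res2 = vst(k2, sf(k), dispersion=res.dispersion)
    assert res2.t.iloc[0, 0] > res.t.iloc[0, 0]


def test_vst_flattens_nb_variance_mean_slope(rng):
    """On a 500-row NB matrix (alpha=0.1) spanning a wide mean range, the
    regression slope of per-row variance of t on per-row mean of t is
    within +/-0.1 of zero."""
    n, reps, alpha = 500, 6, 0.1
    means = np.exp(rng.uniform(np.log(5), np.log(5000), n))
    r = 1 / alpha
    counts = rng.negative_binomial(r, r / (r + means[:, None]),
                                   size=(n, reps))
    k = pd.DataFrame(counts, columns=[f"s{i}" for i in range(reps)])
    res = vst(k, s=pd.Series(1.0, index=k.columns), dispersion=alpha)
    t = res.t.to_numpy()
    slope = np.polyfit(t.mean(axis=1), t.var(axis=1, ddof=1), 1)[0]
    assert abs(slope) <= 0.1


def test_blind_dispersion_moment_estimate_recovers_alpha(rng):
    n, reps, alpha = 2000, 8, 0.2
    means = np.exp(rng.uniform(np.log(50), np.log(2000), n))
    r = 1 / alpha
    q = rng.negative_binomial(r, r / (r + means[:, None]), size=(n, reps))
    est = fit_common_dispersion(q.astype(float))
    assert est == pytest.approx(alpha, rel=0.35)


def test_hca_duplicated_column_merges_at_height_zero():
    k = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0],
                      "c": [9.0, 0.0, 3.0]})
    res = hca(k)
    assert res.organ_linkage[0, 2] == 0.0
    assert first_merge_pair(res.organ_linkage, res.organ_labels, "a", "b")


def test_hca_invariant_to_row_permutation(fixture_run, rng):
    t = fixture_run["vst"].t
    perm = rng.permutation(len(t))
    res1 = hca(t)
    res2 = hca(t.iloc[perm])
    assert res1.organ_order == res2.organ_order
    assert np.allclose(np.sort(res1.organ_linkage[:, 2]),
                       np.sort(res2.organ_linkage[:, 2]))


def test_hca_same_profile_organs_are_sisters(rng):
    """Two organs generated from one expression profile cluster as sisters
    against two organs from a different profile."""
    base1 = np.exp(rng.uniform(np.log(10), np.log(1000), 60))
    base2 = np.exp(rng.uniform(np.log(10), np.log(1000), 60))
    def noisy(base):
        return rng.poisson(base)
    k = pd.DataFrame({"p1a": noisy(base1), "p1b": noisy(base1),
                      "p2a": noisy(base2), "p2b": noisy(base2)})
    res = hca(vst(k).t)
    assert first_merge_pair(res.organ_linkage, res.organ_labels, "p1a", "p1b")
    assert first_merge_pair(res.organ_linkage, res.organ_labels, "p2a", "p2b")


def test_hca_rejects_degenerate_input():
    with pytest.raises(ValueError):
        hca(pd.DataFrame({"a": [1.0, 2.0]}))


def test_newick_export_contains_all_leaves(fixture_run):
    res = fixture_run["hca"]
    nwk = res.organ_newick()
    assert nwk.endswith(";")
    for organ in ("LL", "FL", "RL", "SL"):
        assert organ in nwk


def test_merge_heights_non_decreasing(fixture_run):
    heights = fixture_run["hca"].family_linkage[:, 2]
    assert np.all(np.diff(heights) >= -1e-9)


def test_fixture_organ_tree_reports_leaf_root_adjacency(fixture_run):
    """Soft qualitative check: on the bundled tables, leaf (LL) and root
    (RL) accumulation patterns cluster together before joining flower or
    seedling."""
    assert isinstance(fixture_run["leaf_root_sisters"], bool)
    assert fixture_run["leaf_root_sisters"]
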
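import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonflux import (
    CodingSequence,
    SpeedProfile,
    bin_genome,
    bundled_cai_weights,
    cai,
    cai_weights_from_counts,
    correlate,
    group_compare,
    profile,
    rank_and_slice,
    rate_table,
    sensitivity,
    toy_pool,
    toy_species,
)
from codonflux.sensitivity import SensitivityResult


def _prof(times, gene="g", condition="c"):
    t = np.asarray(times, dtype=float)
    return SpeedProfile(gene_id=gene, condition=condition, raw_times=t, smoothed_times=t, window=1)


# ---------------------------------------------------------------------------
# The sensitivity measure
# ---------------------------------------------------------------------------

def test_identical_profiles_have_zero_sensitivity():
    p = _prof([1.0, 2.0, 3.0])
    assert sensitivity(p, _prof([1.0, 2.0, 3.0], condition="c2")).S == 0.0


def test_sensitivity_is_symmetric():
    p = _prof([1.0, 2.0], condition="c1")
    q = _prof([2.0, 5.0], condition="c2")
    assert sensitivity(p, q).S == sensitivity(q, p).S


def test_sensitivity_hand_computed_length_five():
    p = _prof([1.0, 2.0, 3.0, 4.0, 5.0], condition="c1")
    q = _prof([2.0, 2.0, 1.0, 6.0, 5.0], condition="c2")
    # |diffs| = 1, 0, 2, 2, 0 -> mean 1.0
    r = sensitivity(p, q)
    assert r.S == pytest.approx(1.0)
    assert r.l == 5
    assert r.condition_pair == ("c1", "c2")


def test_sensitivity_requires_matching_profiles():
    with pytest.raises(ValueError):
        sensitivity(_prof([1.0]), _prof([1.0, 2.0]))
    with pytest.raises(ValueError):
        sensitivity(_prof([1.0], gene="a"), _prof([1.0], gene="b"))


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=0.01, max_value=50.0),
            st.floats(min_value=0.01, max_value=50.0),
            st.floats(min_value=0.01, max_value=50.0),
        ),
        min_size=1,
        max_size=40,
    )
)
@settings(deadline=None, max_examples=100)
def test_metric_axioms_on_random_profile_triples(rows):
    a = _prof([r[0] for r in rows], condition="a")
    b = _prof([r[1] for r in rows], condition="b")
    c = _prof([r[2] for r in rows], condition="c")
    s_ab = sensitivity(a, b).S
    s_ba = sensitivity(b, a).S
    s_ac = sensitivity(a, c).S
    s_cb = sensitivity(c, b).S
    assert s_ab >= 0.0
    assert s_ab == s_ba
    if s_ab == 0.0:
        assert np.array_equal(a.smoothed_times, b.smoothed_times)
    assert s_ab <= s_ac + s_cb + 1e-9


def test_uniform_time_scaling_scales_sensitivity_linearly():
    p = _prof([1.0, 3.0], condition="c1")
    q = _prof([2.0, 2.5], condition="c2")
    base = sensitivity(p, q).S
    k = 7.0
    pk = _prof([k * 1.0, k * 3.0], condition="c1")
    qk = _prof([k * 2.0, k * 2.5], condition="c2")
    assert sensitivity(pk, qk).S == pytest.approx(k * base, rel=1e-12)


def test_genes_without_perturbed_codons_have_zero_sensitivity():
    """The toy pool is normalization-balanced for Gly2: changing only that
    isoacceptor's availability leaves every non-Gly codon rate unchanged
    in exact arithmetic, so a gene without GGA/GGG has S = 0 (up to one
    ulp of the profile values in floats)."""
    from codonflux import TRNAPool

    species = list(toy_species())
    ref_pool = toy_pool("ref")
    conc = dict(ref_pool.concentration)
    conc["Gly2"] *= 0.3
    ref = rate_table(ref_pool, species)
    alt = rate_table(TRNAPool("gly_perturbed", conc), species)
    gene = CodingSequence("g", "ATG" + "CTGCTTCGA" * 8 + "TAA", strict=False)
    p_ref, p_alt = profile(gene, ref), profile(gene, alt)
    S = sensitivity(p_ref, p_alt).S
    assert S <= np.finfo(float).eps * p_ref.smoothed_times.mean()
    # while a Gly-using gene does respond
    gly_gene = CodingSequence("g2", "ATG" + "GGAGGG" * 12 + "TAA", strict=False)
    assert sensitivity(profile(gly_gene, ref), profile(gly_gene, alt)).S > 1e-6


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _results(values, pair=("c1", "c2")):
    return [
        SensitivityResult(gene_id=f"g{i:02d}", condition_pair=pair, S=v, l=10)
        for i, v in enumerate(values)
    ]


def test_rank_and_slice_ten_genes_ten_percent():
    res = _results([0.1 * i for i in range(10)])
    most, least = rank_and_slice(res, fraction=0.1)
    assert most == ["g09"]
    assert least == ["g00"]


def test_rank_and_slice_tie_break_lexicographic():
    res = _results([1.0] * 10)
    most, least = rank_and_slice(res, fraction=0.1)
    assert most == ["g00"] and least == ["g00"]
    # deterministic across runs
    assert rank_and_slice(res, fraction=0.1) == rank_and_slice(list(reversed(res)), fraction=0.1)


def test_rank_and_slice_excludes_untranslated_and_pseudo():
    res = _results([0.1 * i for i in range(10)])
    cats = {"g09": "untranslated", "g08": "pseudo"}
    most, _ = rank_and_slice(res, fraction=0.1, categories=cats)
    assert most == ["g07"]


def test_leu_rich_twin_ranks_above_its_paralog():
    """Perturbing Leu isoacceptor charging ranks the CUU/CUC/CUA-using gene
    above the synonymous CUG/UUA/UUG paralog."""
    from codonflux import leucine_twins, toy_starvation_conditions

    species = list(toy_species())
    cs = toy_starvation_conditions()
    rt0 = rate_table(cs.reference, species)
    rt2 = rate_table(cs.pool("t2"), species)
    rng = np.random.default_rng(5)
    sens_gene, rob_gene = leucine_twins(rng)
    results = [
        sensitivity(profile(g, rt0), profile(g, rt2)) for g in (sens_gene, rob_gene)
    ]
    most, least = rank_and_slice(results, fraction=0.5)
    assert most == ["twinL_sensitive"]
    assert least == ["twinL_robust"]


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def test_group_compare_dominant_group_small_p():
    res = _results(list(np.linspace(1.0, 2.0, 20)) + list(np.linspace(0.1, 0.5, 20)))
    a = [f"g{i:02d}" for i in range(20)]
    b = [f"g{i:02d}" for i in range(20, 40)]
    cmp = group_compare(res, a, b)
    assert cmp.pvalue <= 1e-3
    assert cmp.n_a == cmp.n_b == 20


def test_group_compare_null_calibration():
    """Under the null (both groups from one distribution) the rejection
    rate at alpha=0.05 stays near nominal."""
    rng = np.random.default_rng(42)
    reject = 0
    reps = 1000
    for _ in range(reps):
        values = rng.exponential(1.0, size=100)
        res = _results(values)
        a = [f"g{i:02d}" for i in range(50)]
        b = [f"g{i:02d}" for i in range(50, 100)]
        if group_compare(res, a, b).pvalue < 0.05:
            reject += 1
    assert 0.02 < reject / reps < 0.09


def test_group_compare_singleton_vs_singleton_defined():
    res = _results([5.0, 1.0])
    cmp = group_compare(res, ["g00"], ["g01"])
    assert 0.0 < cmp.pvalue <= 1.0
    assert cmp.pvalue == pytest.approx(0.5)  # only two orderings under the exact null


def test_group_compare_validates_groups():
    res = _results([1.0, 2.0])
    with pytest.raises(ValueError):
        group_compare(res, ["g00"], ["g00"])
    with pytest.raises(ValueError):
        group_compare(res, ["absent"], ["g01"])


# ---------------------------------------------------------------------------
# Genome binning
# ---------------------------------------------------------------------------

def test_bin_width_matches_published_partition():
    genes = [CodingSequence("g", "ATGGGGTAA", strict=False, genome_start=1)]
    bins = bin_genome(genes, genome_length=4_639_675, n_bins=200)
    assert len(bins) == 200
    assert bins[0].end - bins[0].start + 1 == 23_198
    assert bins[-1].end == 4_639_675


def test_all_genes_in_one_bin():
    genes = [
        CodingSequence(f"g{i}", "ATGCTGTAA", strict=False, genome_start=10 + i)
        for i in range(4)
    ]
    S = {f"g{i}": float(i) for i in range(4)}
    bins = bin_genome(genes, genome_length=1000, n_bins=10, metrics={"S": S})
    assert bins[0].means["S"] == pytest.approx(np.mean(list(S.values())))
    assert all(b.empty for b in bins[1:])
    assert math.isnan(bins[1].means["S"])


def test_bin_means_match_brute_force(rng):
    starts = rng.integers(1, 10_001, size=50)
    genes = [
        CodingSequence(f"g{i}", "ATGGGGTAA", strict=False, genome_start=int(s))
        for i, s in enumerate(starts)
    ]
    S = {g.id: float(rng.random()) for g in genes}
    n_bins = 7
    bins = bin_genome(genes, genome_length=10_000, n_bins=n_bins, metrics={"S": S})
    width = 10_000 // n_bins
    for b in bins:
        expect = [
            S[g.id]
            for g in genes
            if min((g.genome_start - 1) // width, n_bins - 1) == b.index
        ]
        if expect:
            assert b.means["S"] == pytest.approx(np.mean(expect))
        else:
            assert math.isnan(b.means["S"])


def test_bin_rejects_out_of_range_start():
    genes = [CodingSequence("g", "ATGTAA", strict=False, genome_start=2000)]
    with pytest.raises(ValueError):
        bin_genome(genes, genome_length=1000, n_bins=10)


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------

def test_cai_all_preferred_codons_is_one():
    weights = {"AUG": 1.0, "CUG": 1.0, "AAA": 1.0}
    g = CodingSequence("g", "ATGCTGAAATAA")
    assert cai(g, weights) == pytest.approx(1.0)


def test_cai_closed_form_three_codons():
    weights = {"AUG": 1.0, "CUG": 0.5, "AAA": 0.25}
    g = CodingSequence("g", "ATGCTGAAATAA")
    assert cai(g, weights) == pytest.approx((1.0 * 0.5 * 0.25) ** (1 / 3))


def test_cai_zero_weight_floored():
    weights = {"AUG": 1.0, "CUG": 0.0}
    g = CodingSequence("g", "ATGCTGTAA")
    assert cai(g, weights, zero_floor=0.01) == pytest.approx((1.0 * 0.01) ** 0.5)


def test_cai_weights_from_counts_normalized_per_family():
    counts = {"CUG": 80, "CUU": 20, "AUG": 5}
    w = cai_weights_from_counts(counts)
    assert w["CUG"] == 1.0
    assert w["CUU"] == pytest.approx(0.25)
    assert w["AUG"] == 1.0  # sole synonym


def test_bundled_cai_weights_cover_sense_codons():
    w = bundled_cai_weights()
    assert len(w) == 61
    assert max(w.values()) == 1.0


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def test_correlate_perfect_monotone():
    x = [1.0, 2.0, 3.0, 4.0]
    assert correlate(x, x).rho == pytest.approx(1.0)
    assert correlate(x, [-v for v in x]).rho == pytest.approx(-1.0)


def test_correlate_null_is_small(rng):
    x = rng.permutation(1000).astype(float)
    y = rng.permutation(1000).astype(float)
    res = correlate(x, y)
    assert abs(res.rho) < 0.1
    assert res.r_squared == pytest.approx(res.rho**2)


def test_correlate_constant_input_flagged():
    res = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert not res.defined
    assert math.isnan(res.rho)
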
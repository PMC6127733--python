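"""Allele similarity (HI/H1/H2), individual relatedness, VanRaden kernel.

Expected matrices for the worked example were recomputed by hand from
the haplotype strings: H1 entries are matched-locus fractions, H2
entries are sqrt(sum of squared matched-run lengths / 100), and the
relatedness matrix is the half-sum of the four cross-gamete scores.
"""

import numpy as np
import pytest

from genekin import (
    aggregate_kernel,
    allele_similarity,
    block_relatedness,
    build_blocks_for_scope,
    haplotype_kernel,
    standardize_kernel,
    vanraden_grm,
)
from genekin.similarity_kernels import RelatednessMatrix, _segment_score

from conftest import HAPLOTYPES, make_example_genotypes, random_genotypes

# hand-recomputed worked-example matrices, order hap1..hap4
H1_EXPECTED = np.array(
    [
        [1.0, 0.3, 0.4, 0.3],
        [0.3, 1.0, 0.3, 0.8],
        [0.4, 0.3, 1.0, 0.5],
        [0.3, 0.8, 0.5, 1.0],
    ]
)
H2_EXPECTED = np.sqrt(
    np.array(
        [
            [1.0, 0.03, 0.06, 0.05],
            [0.03, 1.0, 0.09, 0.50],
            [0.06, 0.09, 1.0, 0.13],
            [0.05, 0.50, 0.13, 1.0],
        ]
    )
)
GHAP_EXPECTED = np.array(
    [
        [1.22, 1.05, 0.91, 0.88, 0.74],
        [1.05, 1.17, 0.74, 1.17, 0.86],
        [0.91, 0.74, 1.36, 1.01, 1.18],
        [0.88, 1.17, 1.01, 2.00, 1.30],
        [0.74, 0.86, 1.18, 1.30, 1.30],
    ]
)


@pytest.fixture
def example_block(example_genotypes):
    return build_blocks_for_scope(example_genotypes, np.arange(10), 10)[0]


def _hap_order(block):
    """Indices of hap1..hap4 within the block's first-seen allele table."""
    idx = {h: i for i, h in enumerate(block.allele_table)}
    return [idx[HAPLOTYPES[f"hap{k}"]] for k in range(1, 5)]


class TestWorkedExample:
    def test_h1_matrix(self, example_block):
        order = _hap_order(example_block)
        H1 = allele_similarity(example_block, "H1").values[np.ix_(order, order)]
        assert np.abs(H1 - H1_EXPECTED).max() <= 0.005
        assert H1[0, 1] == pytest.approx(0.3)

    def test_h2_matrix(self, example_block):
        order = _hap_order(example_block)
        H2 = allele_similarity(example_block, "H2").values[np.ix_(order, order)]
        assert np.abs(H2 - H2_EXPECTED).max() <= 0.005
        # the two segment examples: lengths {1, 7} and {2, 3}
        assert H2[1, 3] == pytest.approx(0.71, abs=0.005)
        assert H2[2, 3] == pytest.approx(0.36, abs=0.005)

    def test_hi_is_identity(self, example_block):
        HI = allele_similarity(example_block, "HI").values
        assert np.array_equal(HI, np.eye(4))

    def test_relatedness_matrix(self, example_genotypes, example_block):
        sim = allele_similarity(example_block, "H2")
        G = block_relatedness(example_block, sim, example_genotypes.individual_ids)
        assert np.abs(G.values - GHAP_EXPECTED).max() <= 0.005
        assert G.values[0, 1] == pytest.approx(1.05, abs=0.005)
        assert G.values[0, 0] == pytest.approx(1.22, abs=0.005)
        assert G.values[3, 3] == pytest.approx(2.00, abs=0.005)

    def test_standardized_by_maximum(self, example_genotypes, example_block):
        sim = allele_similarity(example_block, "H2")
        G = block_relatedness(example_block, sim, example_genotypes.individual_ids)
        S = standardize_kernel(G)
        assert S.values.max() == pytest.approx(1.0)
        assert S.values[0, 1] == pytest.approx(G.values[0, 1] / 2.0, abs=1e-12)


def test_segment_scoring_edge_cases():
    a = np.array([1, 0, 1, 1])
    assert _segment_score(a, a) == 16  # one run of 4
    assert _segment_score(a, 1 - a) == 0
    b = np.array([1, 0, 0, 1])  # matched runs {0,1} and {3} -> 4 + 1
    assert _segment_score(a, b) == 5


def test_single_snp_block_collapses_methods():
    rng = np.random.default_rng(2)
    g = random_genotypes(rng, 6, 1)
    g.alleles[:, 0, 0] = [0, 1, 0, 1, 0, 1]
    block = build_blocks_for_scope(g, np.array([0]), 10)[0]
    for method in ("HI", "H1", "H2"):
        M = allele_similarity(block, method).values
        assert np.array_equal(M, np.eye(block.n_alleles))


@pytest.mark.parametrize("seed", range(6))
def test_similarity_invariants_random_blocks(seed):
    """H2 <= H1 elementwise; symmetry, unit diagonal, [0,1] range;
    relatedness diagonal in [1,2]; gamete-swap invariance."""
    rng = np.random.default_rng(seed)
    g = random_genotypes(rng, int(rng.integers(4, 12)), int(rng.integers(2, 15)))
    blocks = build_blocks_for_scope(g, np.arange(g.n_markers), 10)
    for block in blocks:
        H1 = allele_similarity(block, "H1").values
        H2 = allele_similarity(block, "H2").values
        for M in (H1, H2):
            assert np.allclose(M, M.T)
            assert np.allclose(np.diag(M), 1.0)
            assert (M >= 0).all() and (M <= 1 + 1e-12).all()
        assert (H2 <= H1 + 1e-12).all()
        S = block_relatedness(block, allele_similarity(block, "H2"), g.individual_ids)
        d = np.diag(S.values)
        assert (d >= 1 - 1e-12).all() and (d <= 2 + 1e-12).all()
        # diagonal reaches 2 exactly for identical gamete alleles
        same = block.gamete_alleles[:, 0] == block.gamete_alleles[:, 1]
        assert np.allclose(d[same], 2.0)
        assert (d[~same] < 2).all()
        # swapping paternal/maternal slots leaves relatedness unchanged
        swapped = type(block)(
            block.scope_id,
            block.marker_indices,
            block.allele_table,
            block.gamete_alleles[:, ::-1],
        )
        S2 = block_relatedness(
            swapped, allele_similarity(block, "H2"), g.individual_ids
        )
        assert np.allclose(S.values, S2.values)


def test_h1_h2_equality_iff_single_run():
    """H2 equals H1 exactly when all matches form one run covering N or
    there are no matches at all."""
    a = np.array([1, 1, 1, 1])
    assert np.sqrt(_segment_score(a, a) / 16) == 1.0
    b = np.array([1, 1, 0, 0])
    # matches run of length 2 out of 4: H1 = 0.5, H2 = sqrt(4/16) = 0.5
    assert np.sqrt(_segment_score(a, b) / 16) == pytest.approx(0.5)
    c = np.array([1, 0, 1, 0])
    # two split matches: H1 = 0.5 but H2 = sqrt(2)/4 < 0.5
    assert np.sqrt(_segment_score(a, c) / 16) < 0.5


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.integers(1, 40).flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 1), min_size=n, max_size=n),
            st.lists(st.integers(0, 1), min_size=n, max_size=n),
        )
    )
)
def test_segment_score_dominated_by_match_count(pair):
    """sqrt(sum of squared run lengths)/N never exceeds the matched
    fraction, with equality exactly when the matches form at most one
    run (Cauchy-Schwarz on run lengths)."""
    a, b = np.array(pair[0]), np.array(pair[1])
    N = a.size
    h2 = np.sqrt(_segment_score(a, b)) / N
    matches = int((a == b).sum())
    h1 = matches / N
    assert h2 <= h1 + 1e-12
    runs = np.flatnonzero(np.diff(np.concatenate(([0], (a == b).view(np.int8), [0])))).size // 2
    if runs <= 1:
        assert h2 == pytest.approx(h1)
    else:
        assert h2 < h1


def test_aggregate_is_elementwise_mean():
    rng = np.random.default_rng(3)
    ids = [f"s{i}" for i in range(5)]
    mats = []
    for _ in range(100):
        A = rng.normal(size=(5, 5))
        mats.append(RelatednessMatrix(ids, (A + A.T) / 2, "per_block"))
    agg = aggregate_kernel(mats)
    running = np.zeros((5, 5))
    for k, M in enumerate(mats, start=1):
        running += (M.values - running) / k  # independent running mean
    assert np.abs(agg.values - running).max() < 1e-12
    single = aggregate_kernel([mats[0]])
    assert np.array_equal(single.values, mats[0].values)
    two = aggregate_kernel(mats[:2])
    assert np.allclose(two.values, (mats[0].values + mats[1].values) / 2)


def test_aggregate_empty_errors():
    with pytest.raises(ValueError):
        aggregate_kernel([])


def test_standardize_properties():
    ids = ["a", "b"]
    ones = RelatednessMatrix(ids, np.ones((2, 2)), "averaged")
    assert np.array_equal(standardize_kernel(ones).values, np.ones((2, 2)))
    K = RelatednessMatrix(ids, np.array([[2.0, 1.0], [1.0, 4.0]]), "averaged")
    s1 = standardize_kernel(K).values
    s2 = standardize_kernel(RelatednessMatrix(ids, 3.7 * K.values, "averaged")).values
    assert np.allclose(s1, s2)  # scale invariance
    with pytest.raises(ValueError):
        standardize_kernel(RelatednessMatrix(ids, -np.ones((2, 2)), "averaged"))


class TestVanRaden:
    def test_two_individual_hand_calculation(self):
        rng = np.random.default_rng(0)
        g = random_genotypes(rng, 2, 1)
        g.alleles[0, 0] = [1, 1]  # ALT/ALT
        g.alleles[1, 0] = [0, 0]  # REF/REF
        G = vanraden_grm(g)
        # p = 0.5, M = [1, -1], denominator = 2 * 0.25 = 0.5
        assert np.allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_rows_of_centered_product_sum_to_zero(self):
        rng = np.random.default_rng(4)
        g = random_genotypes(rng, 12, 30)
        G = vanraden_grm(g)
        assert np.abs(G.values.sum(axis=1)).max() < 1e-10

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        g = random_genotypes(rng, 20, 50)
        G = vanraden_grm(g)
        dosage = g.alleles.sum(axis=2).astype(float)
        p = dosage.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        denom = 2 * (p[keep] * (1 - p[keep])).sum()
        expected = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                acc = 0.0
                for k in np.flatnonzero(keep):
                    acc += (dosage[i, k] - 2 * p[k]) * (dosage[j, k] - 2 * p[k])
                expected[i, j] = acc / denom
        assert np.abs(G.values - expected).max() < 1e-10

    def test_all_monomorphic_errors(self):
        rng = np.random.default_rng(0)
        g = random_genotypes(rng, 3, 2)
        g.alleles[:] = 1
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_grm(g)


def test_haplotype_kernel_pipeline_symmetry(example_genotypes):
    blocks = build_blocks_for_scope(example_genotypes, np.arange(10), 10)
    K = haplotype_kernel(example_genotypes, blocks, "H1", standardize=True)
    assert np.allclose(K.values, K.values.T)
    assert K.values.max() == pytest.approx(1.0)
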
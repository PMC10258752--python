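import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airepi.errors import (
    EmptyRepertoireError,
    LocusError,
    ValidationError,
)
from airepi.io import Clonotype, Repertoire, downsample_reads
from airepi.metrics import (
    RawRepertoireWarning,
    VUsageMatrix,
    clonality,
    clone_frequencies,
    evenness,
    mean_cdr3_length,
    repertoire_metrics,
    richness,
    shannon_diversity,
    shm_fraction,
    simpson_diversity,
    usage_pca,
    v_usage,
)

from conftest import make_repertoire


# independent oracles: plain-Python compensated summation, no numpy
def shannon_oracle(p):
    return -math.fsum(x * math.log2(x) for x in p)


def simpson_oracle(p):
    return 1.0 - math.fsum(x * x for x in p)


def clonality_oracle(p):
    if len(p) == 1:
        return 1.0
    return 1.0 - shannon_oracle(p) / math.log2(len(p))


def random_prob_vectors(n_vectors=100, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_vectors):
        size = rng.integers(2, 50)
        v = rng.dirichlet(np.full(size, rng.uniform(0.2, 5.0)))
        v = np.clip(v, 1e-12, None)
        yield v / v.sum()


class TestCloneFrequencies:
    def test_two_clones(self):
        p = clone_frequencies(make_repertoire([30, 70]))
        assert np.allclose(p, [0.7, 0.3])  # descending count order

    def test_single_clone(self):
        assert clone_frequencies(make_repertoire([1])).tolist() == [1.0]

    def test_uniform(self):
        p = clone_frequencies(make_repertoire([25, 25, 25, 25]))
        assert p.tolist() == [0.25] * 4

    def test_empty_errors(self):
        with pytest.raises(EmptyRepertoireError):
            clone_frequencies(Repertoire("S1", "TRB"))


class TestShannon:
    def test_one_bit(self):
        assert shannon_diversity([0.5, 0.5]) == 1.0

    def test_degenerate(self):
        assert shannon_diversity([1.0]) == 0.0

    def test_three_clone_value(self):
        assert shannon_diversity([0.5, 0.25, 0.25]) == pytest.approx(1.5, abs=1e-15)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            shannon_diversity([0.5, 0.4])


class TestSimpson:
    def test_single(self):
        assert simpson_diversity([1.0]) == 0.0

    def test_uniform_four(self):
        assert simpson_diversity([0.25] * 4) == pytest.approx(0.75, abs=1e-15)

    def test_skewed(self):
        assert simpson_diversity([0.9, 0.1]) == pytest.approx(0.18, abs=1e-15)

    def test_concentration_flag(self):
        assert simpson_diversity([0.9, 0.1], as_concentration=True) == pytest.approx(
            0.82, abs=1e-15
        )


class TestClonality:
    def test_single_clone_is_one(self):
        assert clonality([1.0]) == 1.0

    @pytest.mark.parametrize("s", [2, 4, 8, 16])
    def test_uniform_is_zero_exact_power_of_two(self, s):
        assert clonality([1.0 / s] * s) == 0.0

    @pytest.mark.parametrize("s", [3, 5, 7, 11])
    def test_uniform_is_zero_any_s(self, s):
        assert abs(clonality([1.0 / s] * s)) < 1e-12

    def test_three_clone_value(self):
        expected = 1 - 1.5 / math.log2(3)
        assert clonality([0.5, 0.25, 0.25]) == pytest.approx(expected, abs=1e-12)
        assert clonality([0.5, 0.25, 0.25]) == pytest.approx(0.05361, abs=5e-6)

    def test_complement_of_evenness(self):
        for p in random_prob_vectors(20, seed=3):
            assert clonality(p) + evenness(p) == pytest.approx(1.0, abs=1e-12)


class TestOracleAgreement:
    def test_formulas_match_high_precision_summation(self):
        for p in random_prob_vectors(100, seed=1):
            assert abs(shannon_diversity(p) - shannon_oracle(p)) < 1e-12
            assert abs(simpson_diversity(p) - simpson_oracle(p)) < 1e-12
            assert abs(clonality(p) - clonality_oracle(p)) < 1e-12


class TestDiversityBounds:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_invariants_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        s = int(rng.integers(1, 40))
        p = rng.dirichlet(np.full(s, 0.7))
        p = np.clip(p, 1e-15, None)
        p = p / p.sum()
        c = clonality(p)
        assert -1e-12 <= c <= 1.0 + 1e-12
        assert shannon_diversity(p) <= math.log2(s) + 1e-9 if s > 1 else True
        assert simpson_diversity(p) <= 1 - 1 / s + 1e-12

    def test_equality_iff_uniform(self):
        s = 8
        uniform = [1.0 / s] * s
        assert shannon_diversity(uniform) == pytest.approx(math.log2(s), abs=1e-12)
        assert simpson_diversity(uniform) == pytest.approx(1 - 1 / s, abs=1e-12)
        tilted = [0.2] + [0.8 / (s - 1)] * (s - 1)
        assert shannon_diversity(tilted) < math.log2(s)
        assert simpson_diversity(tilted) < 1 - 1 / s

    def test_clonality_decreases_when_mass_moves_to_smallest(self):
        # redistribute reads from the largest to the smallest clone
        prev = None
        for delta in range(0, 30, 5):
            counts = np.array([60 - delta, 30, 10 + delta], dtype=float)
            c = clonality(counts / counts.sum())
            if prev is not None:
                assert c < prev
            prev = c


class TestRichness:
    def test_counts_clonotypes(self):
        rep = make_repertoire([5, 4, 3, 2, 1])
        rep.normalized_to = 15
        assert richness(rep) == 5

    def test_after_downsampling(self):
        rep = make_repertoire([100, 100, 100, 1, 1])
        out = downsample_reads(rep, 30, seed=5)
        assert richness(out) == out.richness <= 5

    def test_empty(self):
        assert richness(Repertoire("S1", "TRB")) == 0

    def test_raw_repertoire_warns(self):
        with pytest.warns(RawRepertoireWarning):
            richness(make_repertoire([3, 3]))


class TestMeanCdr3Length:
    def _rep(self, lengths, counts=None):
        counts = counts or [1] * len(lengths)
        clonotypes = {}
        for i, (ln, ct) in enumerate(zip(lengths, counts)):
            nt = "TGT" + "AC" * i + "GGG"
            clonotypes[nt] = Clonotype(
                cdr3_nt=nt, cdr3_aa="A" * ln, read_count=ct
            )
        return Repertoire("S1", "TRB", clonotypes)

    def test_clonotype_weighted(self):
        assert mean_cdr3_length(self._rep([14, 14, 16])) == pytest.approx(14.667, abs=1e-3)

    def test_single(self):
        assert mean_cdr3_length(self._rep([10])) == 10.0

    def test_read_weighted(self):
        rep = self._rep([10, 20], counts=[9, 1])
        assert mean_cdr3_length(rep, weighting="read") == pytest.approx(11.0)

    def test_all_untranslatable_errors(self):
        rep = make_repertoire([3, 3])
        for c in rep.clonotypes.values():
            object.__setattr__(c, "cdr3_aa", "")
        with pytest.raises(EmptyRepertoireError):
            mean_cdr3_length(rep)


class TestShmFraction:
    def _igh(self, identities):
        clonotypes = {}
        for i, ident in enumerate(identities):
            nt = "TGT" + "AG" * i + "GGG"
            clonotypes[nt] = Clonotype(cdr3_nt=nt, read_count=2, v_identity_pct=ident)
        return Repertoire("S1", "IGH", clonotypes)

    def test_strict_threshold_boundary(self):
        # 98.0 is NOT mutated under the strict < 98 rule
        assert shm_fraction(self._igh([100.0, 97.9, 98.0])) == pytest.approx(1 / 3)

    def test_all_germline(self):
        assert shm_fraction(self._igh([100.0, 100.0])) == 0.0

    def test_all_mutated(self):
        assert shm_fraction(self._igh([90.0, 90.0])) == 1.0

    def test_trb_locus_rejected(self):
        with pytest.raises(LocusError):
            shm_fraction(make_repertoire([3], v_identity_pct=95.0))

    def test_missing_identity_listed(self):
        rep = self._igh([99.0])
        key = next(iter(rep.clonotypes))
        object.__setattr__(rep.clonotypes[key], "v_identity_pct", None)
        with pytest.raises(ValidationError, match=key):
            shm_fraction(rep)


class TestVUsage:
    def _rep(self, genes, counts, subject_id="S1"):
        clonotypes = {}
        for i, (g, ct) in enumerate(zip(genes, counts)):
            nt = "TGT" + "CT" * i + "GGG"
            clonotypes[nt] = Clonotype(cdr3_nt=nt, v_gene=g, read_count=ct)
        return Repertoire(subject_id, "TRB", clonotypes)

    def test_clonotype_weighted(self):
        m = v_usage([self._rep(["A", "A", "B"], [1, 1, 1])])
        assert m.v_genes == ["A", "B"]
        assert np.allclose(m.frequencies[0], [2 / 3, 1 / 3])

    def test_disjoint_genes_complementary_zeros(self):
        m = v_usage(
            [
                self._rep(["A", "B"], [1, 1], "S1"),
                self._rep(["C", "D"], [1, 1], "S2"),
            ]
        )
        assert m.frequencies.shape == (2, 4)
        assert np.allclose(m.frequencies[0], [0.5, 0.5, 0, 0])
        assert np.allclose(m.frequencies[1], [0, 0, 0.5, 0.5])

    def test_read_weighted(self):
        m = v_usage([self._rep(["A", "B"], [90, 10])], weighting="read")
        assert np.allclose(m.frequencies[0], [0.9, 0.1])

    def test_rows_sum_to_one(self):
        m = v_usage([self._rep(["A", "B", "C"], [7, 2, 1], f"S{i}") for i in range(4)])
        assert np.allclose(m.frequencies.sum(axis=1), 1.0, atol=1e-9)


class TestUsagePCA:
    def test_identical_rows_no_variance(self):
        freq = np.tile([0.5, 0.3, 0.2], (4, 1))
        m = VUsageMatrix([f"S{i}" for i in range(4)], ["A", "B", "C"], freq)
        scores, loadings, ratio = usage_pca(m)
        assert np.allclose(scores, 0.0)
        assert np.allclose(ratio, 0.0)

    def test_rank_one_structure(self):
        base = np.array([0.5, 0.3, 0.2])
        direction = np.array([0.1, -0.05, -0.05])
        freq = np.array([base + t * direction for t in (-1, -0.5, 0.5, 1)])
        m = VUsageMatrix([f"S{i}" for i in range(4)], ["A", "B", "C"], freq)
        _, _, ratio = usage_pca(m)
        assert ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(7)
        raw = rng.dirichlet(np.ones(6), size=10)
        m = VUsageMatrix([f"S{i}" for i in range(10)], list("ABCDEF"), raw)
        rank = np.linalg.matrix_rank(raw - raw.mean(axis=0))
        scores, loadings, _ = usage_pca(m, n_components=rank)
        centered = raw - raw.mean(axis=0)
        assert np.allclose(scores @ loadings.T, centered, atol=1e-8)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(8)
        raw = rng.dirichlet(np.ones(5), size=12)
        m = VUsageMatrix([f"S{i}" for i in range(12)], list("ABCDE"), raw)
        _, _, ratio = usage_pca(m, n_components=4)
        assert np.all(np.diff(ratio) <= 1e-12)

    def test_single_subject_rejected(self):
        m = VUsageMatrix(["S1"], ["A", "B"], np.array([[0.5, 0.5]]))
        with pytest.raises(ValidationError):
            usage_pca(m)


class TestRepertoireMetricsBundle:
    def test_single_clone_boundary(self):
        m = repertoire_metrics(make_repertoire([42]))
        assert m.clonality == 1.0
        assert m.richness == 1
        assert m.shannon_bits == 0.0

    def test_public_fraction_threshold(self):
        rep = make_repertoire([5, 5])
        keys = sorted(rep.clonotypes)
        object.__setattr__(rep.clonotypes[keys[0]], "pgen", 1e-8)
        object.__setattr__(rep.clonotypes[keys[1]], "pgen", 1e-12)
        m = repertoire_metrics(rep)
        assert m.public_fraction == 0.5
        assert m.mean_pgen == pytest.approx((1e-8 + 1e-12) / 2)

    def test_no_model_no_pgen_fields(self):
        m = repertoire_metrics(make_repertoire([5, 5]))
        assert m.mean_pgen is None
        assert m.public_fraction is None
        assert m.shannon_bits == 1.0

    def test_downsampled_uniform_clonality_stays_small(self):
        rep = make_repertoire([10] * 1000)
        for seed in range(20):
            out = downsample_reads(rep, 1000, seed=seed)
            m = repertoire_metrics(out)
            assert m.clonality < 0.05
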
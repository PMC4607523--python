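from __future__ import annotations

import numpy as np
import pytest

import oracles
from conftest import make_matrix, random_matrix
from sweepscan.matrix import MISSING, HaplotypeMatrix
from sweepscan.stats import (
    PopSiteCounts,
    dind,
    fay_wu_dh,
    finalize_dind_sentinels,
    ld_r2,
    nucleotide_diversity,
    site_counts,
    sliding_dh,
    tajimas_d,
    watterson_theta,
    weir_cockerham_fst,
)


class TestNucleotideDiversity:
    def test_identical_haplotypes_zero(self):
        m = make_matrix(np.zeros((6, 10), dtype=int))
        assert nucleotide_diversity(m) == 0.0

    def test_single_pair_three_differences(self):
        m = make_matrix([[0, 0, 0, 1, 0], [1, 1, 0, 0, 0]])
        assert nucleotide_diversity(m) == 3.0

    def test_matches_bruteforce_double_loop(self, rng):
        for _ in range(20):
            m = random_matrix(rng, n_hap=6, n_sites=12)
            assert nucleotide_diversity(m) == pytest.approx(
                oracles.pi_bruteforce(m.alleles), abs=1e-10
            )

    def test_requires_two_haplotypes(self):
        m = make_matrix([[0, 1], [0, 0]])
        with pytest.raises((ValueError, KeyError)):
            nucleotide_diversity(m, population="nope")

    def test_missing_data_rescaled(self):
        # pair differs at 1 of 2 comparable sites out of 4 -> 1 * 4/2 = 2
        a = np.array([[0, 0, 1, 0], [1, 0, MISSING, MISSING]], dtype=np.int8)
        m = make_matrix(a)
        assert nucleotide_diversity(m) == pytest.approx(2.0)


class TestWattersonTheta:
    def test_n2_equals_s(self):
        m = make_matrix([[0] * 5, [1] * 5])
        assert watterson_theta(m) == 5.0

    def test_no_segregating_sites(self):
        m = make_matrix(np.ones((4, 3), dtype=int))
        assert watterson_theta(m) == 0.0

    def test_n4_denominator(self):
        alleles = np.zeros((4, 6), dtype=int)
        alleles[0, :] = 1  # 6 singleton sites
        m = make_matrix(alleles)
        assert watterson_theta(m) == pytest.approx(6 / (1 + 0.5 + 1 / 3))

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            m = random_matrix(rng)
            assert watterson_theta(m) == pytest.approx(
                oracles.watterson_bruteforce(m.alleles), abs=1e-10
            )


class TestTajimasD:
    def test_n2_always_zero(self, rng):
        for _ in range(5):
            m = random_matrix(rng, n_hap=2, n_sites=20)
            d = tajimas_d(m)
            if not np.isnan(d):
                assert d == pytest.approx(0.0, abs=1e-12)

    def test_undefined_when_monomorphic(self):
        m = make_matrix(np.zeros((6, 4), dtype=int))
        assert np.isnan(tajimas_d(m))

    def test_matches_independent_evaluation(self, rng):
        for _ in range(20):
            m = random_matrix(rng, n_hap=10, n_sites=40)
            assert tajimas_d(m) == pytest.approx(
                oracles.tajimas_d_bruteforce(m.alleles), abs=1e-10
            )


class TestFayWuDH:
    def test_undefined_when_no_segregating(self):
        m = make_matrix(np.zeros((4, 5), dtype=int))
        assert np.isnan(fay_wu_dh(m))

    def test_numerator_matches_sfs_oracle(self):
        alleles = np.array(
            [
                [0, 1, 1, 0, 1, 0],
                [0, 1, 0, 0, 1, 1],
                [1, 1, 0, 0, 1, 0],
                [0, 0, 0, 1, 1, 0],
            ],
            dtype=np.int8,
        )
        m = make_matrix(alleles)
        dh = fay_wu_dh(m)
        full = oracles.dh_bruteforce(m.alleles)
        assert dh == pytest.approx(full, abs=1e-10)

    def test_matches_bruteforce_random(self, rng):
        for _ in range(20):
            m = random_matrix(rng)
            got = fay_wu_dh(m)
            want = oracles.dh_bruteforce(m.alleles)
            assert got == pytest.approx(want, abs=1e-10)

    def test_unpolarized_sites_excluded_with_warning(self):
        alleles = np.array([[0, 1], [1, 1], [0, 0], [1, 0]], dtype=np.int8)
        m = make_matrix(alleles)
        m.polarized[1] = False
        with pytest.warns(UserWarning, match="unpolarized"):
            got = fay_wu_dh(m)
        only_first = oracles.dh_bruteforce(m.alleles[:, [0]])
        assert got == pytest.approx(only_first, abs=1e-10)


class TestSlidingDH:
    def test_window_count_region_10kb(self, neutral_matrix):
        wins = sliding_dh(neutral_matrix, 1, 10_000, window=5_000, step=500)
        assert len(wins) == 11
        assert wins[0].start == 1 and wins[0].end == 5_000
        assert wins[-1].end == 10_000

    def test_window_lengths_fixed(self, neutral_matrix):
        wins = sliding_dh(neutral_matrix, 1, 10_000, window=5_000, step=500)
        assert all(w.end - w.start + 1 == 5_000 for w in wins)

    def test_empty_window_undefined(self):
        m = make_matrix([[0, 1], [1, 0]], positions=[5, 9000])
        wins = sliding_dh(m, 1, 10_000, window=5_000, step=500, min_snps=1)
        # windows covering neither SNP are undefined
        bare = [w for w in wins if w.n_snps == 0]
        assert bare and all(not w.defined for w in bare)

    def test_whole_region_window_equals_global(self, neutral_matrix):
        m = neutral_matrix
        wins = sliding_dh(m, 1, 200_000, window=300_000, step=500)
        assert len(wins) == 1
        assert wins[0].value == pytest.approx(fay_wu_dh(m), abs=1e-12)

    def test_window_must_exceed_step(self, neutral_matrix):
        with pytest.raises(ValueError):
            sliding_dh(neutral_matrix, 1, 10_000, window=100, step=500)


class TestWeirCockerhamFst:
    def test_fixed_difference_is_one(self):
        a = PopSiteCounts(10, 0.0, 0.0)
        b = PopSiteCounts(10, 1.0, 0.0)
        assert weir_cockerham_fst(a, b) == pytest.approx(1.0)

    def test_identical_hw_populations_nonpositive(self):
        a = PopSiteCounts(20, 0.4, 2 * 0.4 * 0.6)
        b = PopSiteCounts(20, 0.4, 2 * 0.4 * 0.6)
        assert weir_cockerham_fst(a, b) <= 0.0

    def test_toy_counts_match_formula_oracle(self):
        got = weir_cockerham_fst(
            PopSiteCounts(10, 0.3, 0.42), PopSiteCounts(10, 0.7, 0.42)
        )
        want = oracles.wc_fst_bruteforce(10, 0.3, 0.42, 10, 0.7, 0.42)
        assert got == pytest.approx(want, abs=1e-12)

    def test_monomorphic_undefined(self):
        a = PopSiteCounts(10, 0.0, 0.0)
        b = PopSiteCounts(10, 0.0, 0.0)
        assert np.isnan(weir_cockerham_fst(a, b))

    def test_random_sites_match_oracle(self, rng):
        for _ in range(25):
            na, nb = int(rng.integers(5, 30)), int(rng.integers(5, 30))
            pa, pb = rng.uniform(0.05, 0.95, 2)
            ha = float(rng.uniform(0, 2 * min(pa, 1 - pa)))
            hb = float(rng.uniform(0, 2 * min(pb, 1 - pb)))
            got = weir_cockerham_fst(
                PopSiteCounts(na, pa, ha), PopSiteCounts(nb, pb, hb)
            )
            want = oracles.wc_fst_bruteforce(na, pa, ha, nb, pb, hb)
            assert got == pytest.approx(want, abs=1e-10)

    def test_bounds(self, rng):
        for _ in range(50):
            na, nb = int(rng.integers(2, 40)), int(rng.integers(2, 40))
            pa, pb = rng.uniform(0, 1, 2)
            got = weir_cockerham_fst(
                PopSiteCounts(na, pa, 0.0), PopSiteCounts(nb, pb, 0.0)
            )
            if not np.isnan(got):
                assert -1.0 <= got <= 1.0

    def test_site_counts_helper(self):
        alleles = np.array(
            [[0, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8
        )  # 2 diploids
        m = make_matrix(alleles)
        c = site_counts(m, 0, "pop0")
        assert c.n == 2
        assert c.p == pytest.approx(0.25)
        assert c.het == pytest.approx(0.5)


class TestDind:
    def _matrix_with_flanks(self, rng, n_hap=8, n_flank=60):
        freqs = rng.uniform(0.2, 0.8, size=n_flank + 1)
        alleles = (rng.random((n_hap, n_flank + 1)) < freqs).astype(np.int8)
        focal = n_flank // 2
        # force both allele classes at focal to have >= 2 members
        alleles[:, focal] = 0
        alleles[: n_hap // 2, focal] = 1
        return make_matrix(alleles), focal

    def test_matches_bruteforce_pairwise_loops(self, rng):
        m, focal = self._matrix_with_flanks(rng)
        res = dind(m, focal, flank_total=40)
        assert res.computed
        # recover the flank columns: nearest 20 segregating either side
        seg = [
            j for j in range(m.n_sites)
            if j != focal and 0 < m.alleles[:, j].sum() < m.n_haplotypes
        ]
        below = [j for j in seg if j < focal][-20:]
        above = [j for j in seg if j > focal][:20]
        flanks = below + above
        ipa, ipd = oracles.dind_bruteforce(m.alleles, focal, flanks)
        assert res.i_pi_a == pytest.approx(ipa, abs=1e-10)
        assert res.i_pi_d == pytest.approx(ipd, abs=1e-10)
        if ipd > 0:
            assert res.dind == pytest.approx(ipa / ipd, abs=1e-10)

    def test_identical_derived_class_sentinel(self, rng):
        m, focal = self._matrix_with_flanks(rng)
        carriers = np.nonzero(m.alleles[:, focal] == 1)[0]
        m.alleles[carriers] = m.alleles[carriers[0]][None, :]
        res = dind(m, focal, flank_total=40)
        assert res.computed and res.sentinel_flag
        assert res.i_pi_d == 0.0

    def test_identical_ancestral_class_dind_zero(self, rng):
        m, focal = self._matrix_with_flanks(rng)
        anc = np.nonzero(m.alleles[:, focal] == 0)[0]
        m.alleles[anc] = m.alleles[anc[0]][None, :]
        res = dind(m, focal, flank_total=40)
        if res.computed and not res.sentinel_flag:
            assert res.dind == 0.0

    def test_too_few_flanks_not_computed(self, rng):
        m, focal = self._matrix_with_flanks(rng, n_flank=20)
        res = dind(m, focal, flank_total=40)
        assert not res.computed

    def test_flank_borrowing_near_edge(self, rng):
        m, _ = self._matrix_with_flanks(rng, n_flank=80)
        # focal near the left edge: flank must borrow from the right side
        seg = np.nonzero(
            (m.alleles.sum(axis=0) > 0)
            & (m.alleles.sum(axis=0) < m.n_haplotypes)
        )[0]
        focal = int(seg[2])
        m.alleles[:, focal] = 0
        m.alleles[: m.n_haplotypes // 2, focal] = 1
        res = dind(m, focal, flank_total=40)
        assert res.computed
        assert res.n_flank_used == 40

    def test_small_allele_class_not_computed(self, rng):
        m, focal = self._matrix_with_flanks(rng)
        m.alleles[:, focal] = 0
        m.alleles[0, focal] = 1  # derived singleton
        res = dind(m, focal, flank_total=40)
        assert not res.computed


class TestFinalizeSentinels:
    def _res(self, value, sentinel=False, computed=True):
        from sweepscan.stats import DindResult

        return DindResult(0, "x", 1, 0.5, 1.0, 0.0 if sentinel else 1.0,
                          value, sentinel, 40, computed)

    def test_sentinels_get_max_plus_20(self):
        rs = [self._res(1.2), self._res(3.4),
              self._res(float("nan"), sentinel=True),
              self._res(float("nan"), sentinel=True)]
        out = finalize_dind_sentinels(rs)
        assert out[2].dind == pytest.approx(23.4)
        assert out[3].dind == pytest.approx(23.4)

    def test_no_sentinels_identity(self):
        rs = [self._res(1.0), self._res(2.0)]
        assert finalize_dind_sentinels(rs) == rs

    def test_single_finite_zero(self):
        rs = [self._res(0.0), self._res(float("nan"), sentinel=True)]
        out = finalize_dind_sentinels(rs)
        assert out[1].dind == pytest.approx(20.0)

    def test_all_sentinel_raises(self):
        rs = [self._res(float("nan"), sentinel=True)]
        with pytest.raises(ValueError):
            finalize_dind_sentinels(rs)


class TestLdR2:
    def test_duplicated_column_one(self):
        x = np.array([0, 1, 0, 1, 1, 0], dtype=np.int8)
        assert ld_r2(x, x.copy()) == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        x = np.zeros(6, dtype=np.int8)
        y = np.array([0, 1, 0, 1, 1, 0], dtype=np.int8)
        assert np.isnan(ld_r2(x, y))

    def test_toy_counts_match_enumeration(self):
        # AB=4, Ab=1, aB=1, ab=4
        x = np.array([1] * 5 + [0] * 5, dtype=np.int8)
        y = np.array([1] * 4 + [0, 1] + [0] * 4, dtype=np.int8)
        assert ld_r2(x, y) == pytest.approx(
            oracles.r2_bruteforce(x, y), abs=1e-12
        )

    def test_bounds_random(self, rng):
        for _ in range(30):
            x = (rng.random(20) < 0.5).astype(np.int8)
            y = (rng.random(20) < 0.5).astype(np.int8)
            r = ld_r2(x, y)
            if not np.isnan(r):
                assert 0.0 <= r <= 1.0 + 1e-12


class TestPermutationInvariance:
    def test_row_shuffle_changes_nothing(self, rng):
        m = random_matrix(rng, n_hap=8, n_sites=30)
        perm = rng.permutation(8)
        # only permute within sample pairs structure: rebuild as new matrix
        shuffled = make_matrix(m.alleles[perm], positions=m.positions)
        assert nucleotide_diversity(m) == pytest.approx(
            nucleotide_diversity(shuffled), abs=1e-12
        )
        assert watterson_theta(m) == watterson_theta(shuffled)
        d1, d2 = tajimas_d(m), tajimas_d(shuffled)
        assert d1 == pytest.approx(d2, abs=1e-12)
        h1, h2 = fay_wu_dh(m), fay_wu_dh(shuffled)
        assert h1 == pytest.approx(h2, abs=1e-12)
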
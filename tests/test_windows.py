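"""Windowed diversity statistics against brute-force pairwise oracles."""

import itertools

import numpy as np
import pytest

from introkit import windows as pw
from introkit.genio import SampleTable, SnpWindow, windows_by_bp
from conftest import make_matrix


def brute_pi_count(hap):
    """Mean pairwise difference count over all haplotype pairs (O(n^2))."""
    n = hap.shape[0]
    total = sum(np.sum(hap[i] != hap[j])
                for i, j in itertools.combinations(range(n), 2))
    return total / (n * (n - 1) / 2)


def brute_dxy_count(hap_a, hap_b):
    """Mean cross-population pairwise difference count (O(nA*nB))."""
    total = sum(np.sum(a != b) for a in hap_a for b in hap_b)
    return total / (hap_a.shape[0] * hap_b.shape[0])


def whole_window(matrix):
    return SnpWindow("chr1", 0, matrix.n_sites,
                     int(matrix.pos[0]), int(matrix.pos[-1]))


def independent_tajima(hap):
    """Separate implementation of Tajima's D from first principles."""
    n, S_sites = hap.shape
    freq = hap.mean(axis=0)
    seg = (freq > 0) & (freq < 1)
    S = int(seg.sum())
    pi = brute_pi_count(hap)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestPi:
    def test_single_difference_in_100bp(self):
        hap = np.array([[0], [1]], dtype=np.int8)
        m = make_matrix(hap, pos=[50])
        w = SnpWindow("chr1", 0, 1, 1, 100)
        assert pw.window_pi(m, ["s0"], w) == pytest.approx(0.01)

    def test_monomorphic_window_zero(self):
        m = make_matrix(np.zeros((4, 10), dtype=np.int8))
        assert pw.window_pi(m, ["s0", "s1"], whole_window(m)) == 0.0

    def test_matches_pairwise_oracle(self, random_matrix):
        w = whole_window(random_matrix)
        L = w.end_bp - w.start_bp + 1
        got = pw.window_pi(random_matrix, random_matrix.sample_ids, w)
        expected = brute_pi_count(random_matrix.alleles) / L
        assert got == pytest.approx(expected, abs=1e-12)


class TestDxy:
    def test_fixed_differences(self):
        hap = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        m = make_matrix(hap, pos=[10, 20])
        w = SnpWindow("chr1", 0, 2, 1, 100)
        assert pw.window_dxy(m, ["s0"], ["s1"], w) == pytest.approx(0.02)

    def test_matches_pairwise_oracle(self, random_matrix):
        ids = random_matrix.sample_ids
        a_ids, b_ids = ids[:5], ids[5:]
        w = whole_window(random_matrix)
        L = w.end_bp - w.start_bp + 1
        rows_a = random_matrix.rows_for_samples(a_ids)
        rows_b = random_matrix.rows_for_samples(b_ids)
        expected = brute_dxy_count(random_matrix.alleles[rows_a],
                                   random_matrix.alleles[rows_b]) / L
        got = pw.window_dxy(random_matrix, a_ids, b_ids, w)
        assert got == pytest.approx(expected, abs=1e-12)


class TestHudsonFst:
    def test_fixed_difference_gives_one(self):
        fst, floored = pw.window_fst_hudson(0.0, 0.0, 1.0)
        assert fst == 1.0 and not floored

    def test_zero_dxy_undefined(self):
        fst, _ = pw.window_fst_hudson(0.0, 0.0, 0.0)
        assert np.isnan(fst)

    def test_negative_floored(self):
        fst, floored = pw.window_fst_hudson(1.0, 1.0, 0.9)
        assert fst == 0.0 and floored

    def test_identical_populations_near_zero(self):
        from introkit import simulate as sim
        model = sim.PopModel(("a",), (0.2,), (120,))
        m, _ = sim.simulate_reference_panels(model, 5000, seed=13)
        ids = m.sample_ids
        w = whole_window(m)
        a, b = ids[:30], ids[30:]
        pa = pw.window_pi(m, a, w)
        pb = pw.window_pi(m, b, w)
        dxy = pw.window_dxy(m, a, b, w)
        L = w.end_bp - w.start_bp + 1
        fst, _ = pw.window_fst_hudson(pa * L, pb * L, dxy * L)
        assert fst <= 0.02


class TestGlobalFst:
    def test_duplicated_population_zero(self, random_matrix):
        # same haplotypes under two labels: WC total is floored to 0
        table = SampleTable.from_records(
            [(s, "one", "reference") for s in random_matrix.sample_ids])
        m2 = random_matrix.take_samples(random_matrix.sample_ids)
        m2.sample_ids = [f"copy_{s}" for s in random_matrix.sample_ids]
        from introkit.genio import merge_haplotypes
        merged = merge_haplotypes([random_matrix, m2])
        table = SampleTable.from_records(
            [(s, "one", "reference") for s in random_matrix.sample_ids]
            + [(f"copy_{s}", "two", "reference") for s in random_matrix.sample_ids])
        fst = pw.pairwise_fst_global(merged, table)
        assert abs(fst.loc["one", "two"]) < 1e-6

    def test_opposite_fixation_gives_one(self):
        hap = np.vstack([np.zeros((4, 20)), np.ones((4, 20))]).astype(np.int8)
        m = make_matrix(hap)
        table = SampleTable.from_records(
            [(f"s{i}", "a" if i < 2 else "b", "reference") for i in range(4)])
        fst = pw.pairwise_fst_global(m, table)
        assert fst.loc["a", "b"] == pytest.approx(1.0)

    def test_matrix_symmetric_zero_diagonal(self, random_matrix):
        table = SampleTable.from_records(
            [(s, "a" if i < 5 else "b", "reference")
             for i, s in enumerate(random_matrix.sample_ids)])
        fst = pw.pairwise_fst_global(random_matrix, table)
        assert fst.loc["a", "a"] == 0.0
        assert fst.loc["a", "b"] == fst.loc["b", "a"]


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        m = make_matrix(np.zeros((4, 10), dtype=np.int8))
        assert np.isnan(pw.tajimas_d(m, ["s0", "s1"], whole_window(m)))

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(8)
        hap = (rng.random((4, 10)) < 0.4).astype(np.int8)
        while not ((hap.mean(0) > 0) & (hap.mean(0) < 1)).any():
            hap = (rng.random((4, 10)) < 0.4).astype(np.int8)
        m = make_matrix(hap)
        got = pw.tajimas_d(m, ["s0", "s1"], whole_window(m))
        assert got == pytest.approx(independent_tajima(hap), abs=1e-12)

    def test_matches_oracle_larger_sample(self, random_matrix):
        got = pw.tajimas_d(random_matrix, random_matrix.sample_ids,
                           whole_window(random_matrix))
        assert got == pytest.approx(
            independent_tajima(random_matrix.alleles), abs=1e-12)

    def test_sign_behaviour(self):
        # intermediate-frequency excess -> positive; singletons -> negative
        n = 20
        rng = np.random.default_rng(9)
        mid = np.zeros((n, 50), dtype=np.int8)
        for j in range(50):
            mid[rng.choice(n, n // 2, replace=False), j] = 1
        m_mid = make_matrix(mid)
        assert pw.tajimas_d(m_mid, m_mid.sample_ids, whole_window(m_mid)) > 0
        singles = np.zeros((n, 50), dtype=np.int8)
        for j in range(50):
            singles[j % n, j] = 1
        m_s = make_matrix(singles)
        assert pw.tajimas_d(m_s, m_s.sample_ids, whole_window(m_s)) < 0


@pytest.fixture(scope="module")
def scan_setup():
    from introkit import simulate as sim
    model = sim.PopModel(("a", "b"), (0.2, 0.2), (20, 20))
    m, _ = sim.simulate_reference_panels(model, 3000, bp_per_site=100, seed=4)
    table = SampleTable.from_records(
        [(s, s.rsplit("_", 1)[0], "reference") for s in m.sample_ids])
    return m, table


class TestSlidingScan:
    def test_min_snp_exclusion_boundary(self, scan_setup):
        m, table = scan_setup
        df = pw.sliding_scan(m, table, size=1000, step=500, min_snps=10)
        # 100 bp spacing -> 10 or 11 SNPs per 1 kb window: all computed
        assert not df["excluded"].any()
        df9 = pw.sliding_scan(m, table, size=1000, step=500, min_snps=12)
        assert df9.loc[df9["snp_count"] < 12, "excluded"].all()
        assert df9.loc[df9["snp_count"] < 12, "pi_a"].isna().all()
        # windows at exactly the threshold are computed
        at = df9[df9["snp_count"] >= 12]
        assert at["pi_a"].notna().all()

    def test_shift_invariance_with_data_anchor(self, scan_setup):
        m, table = scan_setup
        shifted = make_matrix(m.alleles, pos=m.pos + 123_456)
        shifted_table = SampleTable.from_records(
            [(s, "a" if i < 10 else "b", "reference")
             for i, s in enumerate(shifted.sample_ids)])
        # same population split on identical alleles
        base = pw.sliding_scan(m, table, size=1000, step=500, anchor="data")
        moved = pw.sliding_scan(shifted, shifted_table, size=1000, step=500,
                                anchor="data")
        for col in ("pi_a", "pi_b", "dxy_a__b", "fst_a__b", "tajima_d_a"):
            np.testing.assert_allclose(base[col], moved[col], atol=1e-12)

    def test_dxy_exceeds_within_pi_for_diverged_pops(self, scan_setup):
        m, table = scan_setup
        df = pw.sliding_scan(m, table, size=1000, step=500)
        live = df[~df["excluded"]]
        mean_pi = 0.5 * (live["pi_a"] + live["pi_b"])
        assert (live["dxy_a__b"] >= mean_pi).mean() >= 0.95
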
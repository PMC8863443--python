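"""The case/all MIC contrast test, permutation p-values, scans, networks."""
import numpy as np
import pytest
from scipy import stats

import epimic
from epimic.mic import mic as mic_score
from epimic.epistasis import (GenotypeMatrix, PairResult, PhenotypeVector,
                              _pair_seed, delta_mic, enumerate_pairs,
                              filter_significant, network_summary,
                              pairwise_scan, permutation_test)
from epimic.simulate import SimConfig, sample_dataset, table1_model


def _toy_pair(seed=0, n=40, case_signal=True):
    """A toy dataset with a case-only XOR-like dependence planted."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=np.int8)
    y[: n // 2] = 1
    gi = rng.integers(0, 3, size=n)
    gj = rng.integers(0, 3, size=n)
    if case_signal:
        cases = y == 1
        gj[cases] = (2 - gi[cases]) % 3  # deterministic reversal in cases
    return gi.astype(np.int8), gj.astype(np.int8), y


class TestDeltaMic:
    def test_full_sample_as_cases_gives_zero(self):
        gi, gj, _ = _toy_pair(case_signal=False)
        res = delta_mic(gi, gj, np.ones_like(gi))
        assert res.delta == pytest.approx(0.0)
        assert res.mic_all == pytest.approx(res.mic_case)

    def test_recomposes_from_independent_mic_calls(self):
        gi, gj, y = _toy_pair(seed=3)
        res = delta_mic(gi, gj, y)
        mic_all = mic_score(gi, gj).mic
        mic_case = mic_score(gi[y == 1], gj[y == 1]).mic
        assert res.mic_all == pytest.approx(mic_all)
        assert res.mic_case == pytest.approx(mic_case)
        assert res.delta == pytest.approx(abs(mic_all - mic_case) / mic_all,
                                          abs=1e-12)

    def test_symmetric_in_the_two_snps(self):
        gi, gj, y = _toy_pair(seed=4)
        a = delta_mic(gi, gj, y)
        b = delta_mic(gj, gi, y)
        assert a.delta == pytest.approx(b.delta)
        assert a.mic_all == pytest.approx(b.mic_all)

    def test_monomorphic_column_flagged_degenerate(self):
        gi = np.zeros(40, dtype=np.int8)
        gj = np.tile([0, 1, 2, 1], 10).astype(np.int8)
        y = np.tile([0, 1], 20)
        res = delta_mic(gi, gj, y)
        assert res.degenerate
        assert res.delta == 0.0

    def test_missing_rows_dropped_pairwise(self):
        gi, gj, y = _toy_pair(seed=5, n=60)
        gi2 = gi.copy()
        gi2[:6] = -1
        res = delta_mic(gi2, gj, y)
        expected = delta_mic(gi[6:], gj[6:], y[6:])
        assert res.delta == pytest.approx(expected.delta)


class TestPermutationTest:
    def test_deterministic_given_seed(self):
        gi, gj, y = _toy_pair(seed=6, n=60)
        a = permutation_test(gi, gj, y, m=200, seed=42)
        b = permutation_test(gi, gj, y, m=200, seed=42)
        assert a == b

    def test_pvalue_on_the_permutation_grid(self):
        gi, gj, y = _toy_pair(seed=7, n=60, case_signal=False)
        for m in (10, 37, 200):
            p = permutation_test(gi, gj, y, m=m, seed=1).pvalue
            assert 0.0 <= p <= 1.0
            assert (p * m) == pytest.approx(round(p * m), abs=1e-9)

    def test_strong_case_signal_yields_zero_pvalue(self):
        gi, gj, y = _toy_pair(seed=8, n=200)
        res = permutation_test(gi, gj, y, m=200, seed=0)
        assert res.pvalue == 0.0

    def test_conservative_variant_shifts_grid(self):
        gi, gj, y = _toy_pair(seed=8, n=200)
        res = permutation_test(gi, gj, y, m=199, seed=0, conservative=True)
        assert res.pvalue >= 1 / 200

    def test_mic_all_invariant_under_label_permutation(self):
        gi, gj, y = _toy_pair(seed=9, n=80)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(y)
        a = delta_mic(gi, gj, y)
        b = delta_mic(gi, gj, shuffled)
        assert a.mic_all == b.mic_all

    def test_degenerate_pair_reports_p_one(self):
        gi = np.zeros(40, dtype=np.int8)
        gj = np.tile([0, 1], 20).astype(np.int8)
        y = np.tile([0, 1], 20)
        res = permutation_test(gi, gj, y, m=50, seed=0)
        assert res.flag == "degenerate"
        assert res.pvalue == 1.0

    def test_zero_permutations_rejected(self):
        gi, gj, y = _toy_pair()
        with pytest.raises(ValueError):
            permutation_test(gi, gj, y, m=0, seed=0)

    def test_matches_explicit_label_shuffle_oracle(self):
        """Hypergeometric case-count sampling reproduces the p-value of a
        literal shuffle-the-labels permutation test (independent streams,
        so agreement is statistical)."""
        gi, gj, y = _toy_pair(seed=10, n=60)
        # weaken the signal so the p-value is interior
        rng = np.random.default_rng(1)
        flip = rng.random(60) < 0.55
        gj = np.where(flip, rng.integers(0, 3, size=60), gj).astype(np.int8)
        m = 600
        fast = permutation_test(gi, gj, y, m=m, seed=2).pvalue

        obs = delta_mic(gi, gj, y)
        count = 0
        for _ in range(m):
            yp = rng.permutation(y)
            mic_case = mic_score(gi[yp == 1], gj[yp == 1]).mic
            d = abs(obs.mic_all - mic_case) / obs.mic_all
            count += d >= obs.delta
        naive = count / m
        assert abs(fast - naive) < 4 * np.sqrt(0.25 / m) + 0.02


class TestPairwiseScan:
    def _dataset(self, n=60, p=4, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 3, size=(n, p)).astype(np.int8)
        G = GenotypeMatrix(values, [f"S{i}" for i in range(n)],
                           [f"rs{j}" for j in range(p)])
        y = np.tile([0, 1], n // 2)
        return G, y

    @pytest.mark.parametrize("p, expected", [(2, 1), (10, 45)])
    def test_pair_cardinality(self, p, expected):
        G, y = self._dataset(p=p)
        scan = pairwise_scan(G, y, m=20, seed=0)
        assert len(scan.pairs) == expected

    def test_385_ids_enumerate_73920_pairs(self):
        assert len(enumerate_pairs([f"rs{i}" for i in range(385)])) == 73920

    def test_monomorphic_snps_dropped_with_warning(self, caplog):
        G, y = self._dataset(p=4)
        G.values[:, 2] = 1
        with caplog.at_level("WARNING"):
            scan = pairwise_scan(G, y, m=20, seed=0)
        assert len(scan.pairs) == 3
        assert "rs2" in scan.dropped_snps
        assert "monomorphic" in caplog.text

    def test_all_monomorphic_is_error(self):
        G, y = self._dataset(p=3)
        G.values[:, :] = 2
        with pytest.raises(ValueError, match="polymorphic"):
            pairwise_scan(G, y, m=20, seed=0)

    def test_column_order_independent(self):
        G, y = self._dataset(p=4, seed=3)
        scan = pairwise_scan(G, y, m=50, seed=9)
        swapped = GenotypeMatrix(G.values[:, ::-1], G.sample_ids,
                                 G.snp_ids[::-1])
        scan2 = pairwise_scan(swapped, y, m=50, seed=9)
        by_key = {frozenset((r.snp_i, r.snp_j)): r for r in scan2.pairs}
        for r in scan.pairs:
            other = by_key[frozenset((r.snp_i, r.snp_j))]
            assert r.pvalue == other.pvalue
            assert r.delta == other.delta

    def test_pair_seed_symmetric(self):
        assert _pair_seed(5, "a", "b") == _pair_seed(5, "b", "a")
        assert _pair_seed(5, "a", "b") != _pair_seed(6, "a", "b")


def test_null_rejection_rate_within_binomial_band():
    """Under a global null the test rejects at ~alpha: the empirical rate
    over 250 simulated datasets stays inside the exact binomial 99% band."""
    model = table1_model("no_effect", gamma=1.0, maf=0.3)
    alpha, reps, m = 0.05, 250, 200
    rejections = 0
    for rep in range(reps):
        G, y = sample_dataset(SimConfig(model, n=400, p_total=2, seed=rep))
        res = permutation_test(G.values[:, 0], G.values[:, 1], y, m=m,
                               seed=10_000 + rep)
        rejections += res.pvalue <= alpha
    lo = stats.binom.ppf(0.005, reps, alpha) / reps
    hi = stats.binom.ppf(0.995, reps, alpha) / reps
    assert lo <= rejections / reps <= hi


class TestFilterAndNetwork:
    @staticmethod
    def _pair(i, j, p, mic_case=0.5):
        return PairResult(i, j, 0.4, mic_case, 0.2, p, 100)

    def test_nothing_significant_empty(self):
        pairs = [self._pair("a", "b", 1.0), self._pair("b", "c", 1.0)]
        assert filter_significant(pairs, alpha=0.5) == []

    def test_intra_gene_pairs_dropped(self):
        pairs = [self._pair("a", "b", 0.001), self._pair("a", "c", 0.001)]
        gene_map = {"a": "G1", "b": "G1", "c": "G2"}
        kept = filter_significant(pairs, alpha=0.005, gene_map=gene_map)
        assert [(r.snp_i, r.snp_j) for r in kept] == [("a", "c")]

    def test_matches_one_pass_loop_oracle(self):
        rng = np.random.default_rng(21)
        snps = [f"rs{i}" for i in range(12)]
        genes = {s: f"G{rng.integers(0, 4)}" for s in snps}
        pairs = [self._pair(a, b, float(rng.random()))
                 for a, b in enumerate_pairs(snps)]
        alpha = 0.3
        kept = filter_significant(pairs, alpha, gene_map=genes)
        expected = []
        for r in pairs:
            if r.pvalue <= alpha and genes[r.snp_i] != genes[r.snp_j]:
                expected.append((r.snp_i, r.snp_j))
        assert [(r.snp_i, r.snp_j) for r in kept] == expected

    def test_triangle_degrees(self):
        pairs = [self._pair("a", "b", 0.0), self._pair("b", "c", 0.0),
                 self._pair("a", "c", 0.0)]
        net = network_summary(pairs)
        assert set(net.nodes["Degree"]) == {2}
        assert net.average_degree == pytest.approx(2.0)

    def test_star_min_degree_filter(self):
        pairs = [self._pair("hub", f"leaf{i}", 0.0) for i in range(5)]
        net = network_summary(pairs, min_degree=5)
        assert net.nodes["Id"].tolist() == ["hub"]

    def test_edge_weight_is_case_mic(self):
        pairs = [self._pair("a", "b", 0.0, mic_case=0.73)]
        net = network_summary(pairs)
        assert net.edges["Weight"].iloc[0] == pytest.approx(0.73)

    def test_random_network_matches_adjacency_recount(self):
        rng = np.random.default_rng(33)
        snps = [f"rs{i}" for i in range(25)]
        chosen = rng.choice(len(all_pairs := enumerate_pairs(snps)), size=50,
                            replace=False)
        pairs = [self._pair(*all_pairs[k], 0.0) for k in chosen]
        net = network_summary(pairs)
        adjacency = {}
        for r in pairs:
            adjacency.setdefault(r.snp_i, set()).add(r.snp_j)
            adjacency.setdefault(r.snp_j, set()).add(r.snp_i)
        for _, row in net.nodes.iterrows():
            assert row["Degree"] == len(adjacency[row["Id"]])
        assert net.average_degree == pytest.approx(
            2 * 50 / len(adjacency))

    def test_empty_input_empty_outputs(self):
        net = network_summary([])
        assert net.nodes.empty and net.edges.empty
        assert net.average_degree == 0.0


class TestContainers:
    def test_genotype_matrix_validation(self):
        with pytest.raises(ValueError, match="0, 1, 2"):
            GenotypeMatrix([[0, 3], [1, 2]], ["a", "b"], ["s1", "s2"])
        with pytest.raises(ValueError, match="unique"):
            GenotypeMatrix([[0, 1], [1, 2]], ["a", "a"], ["s1", "s2"])

    def test_phenotype_validation(self):
        with pytest.raises(ValueError):
            PhenotypeVector([0, 1, 2])
        assert PhenotypeVector([0, 1, 1]).n_cases == 2

    def test_scan_result_dataframe_columns(self):
        values = np.tile([[0, 0], [1, 1], [2, 2]], (4, 1))
        G = GenotypeMatrix(values, [f"S{i}" for i in range(12)], ["x", "y"])
        scan = pairwise_scan(G, np.tile([0, 1], 6), m=10, seed=0)
        df = scan.to_dataframe()
        assert list(df.columns) == ["snp_i", "snp_j", "mic_all", "mic_case",
                                    "delta_mic", "pvalue", "m", "flag"]
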
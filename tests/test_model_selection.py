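"""BIC sweeps, Bayes factors, inclusion frequencies and censuses."""

import numpy as np
import pytest

import culturenet as cn
from culturenet.model_selection import (
    SelectionTable,
    SignificanceCensus,
    bayes_factor_band,
    sweep_bin,
)
from culturenet.weights import InputError


@pytest.fixture(scope="module")
def planted_table(small_world):
    """Sweeps over bins with signal planted on the spatial adjacency net."""
    panel = cn.make_correlated_panel(small_world, 8, {"S_adj": 0.6}, seed=30)
    bins = []
    for b in range(panel.n_bins):
        y, subs, _ = cn.align_bin(panel, b, list(small_world.networks.values()))
        bins.append(sweep_bin(y, {w.label: w for w in subs},
                              bin_label=str(b), bin_index=b))
    return SelectionTable(bins=bins, matrix_labels=tuple(small_world.networks))


class TestEnumerateModels:
    def test_four_matrices_give_16_specs(self):
        specs = cn.enumerate_models(["a", "b", "c", "d"])
        assert len(specs) == 16
        assert specs[0].name == "null"
        assert len({s.labels for s in specs}) == 16

    def test_single_matrix(self):
        specs = cn.enumerate_models(["w"])
        assert [s.name for s in specs] == ["null", "w"]

    def test_order_is_deterministic(self):
        a = cn.enumerate_models(["S_prox", "SoL_aff", "L_adj", "S_adj"])
        b = cn.enumerate_models(["S_prox", "SoL_aff", "L_adj", "S_adj"])
        assert [s.labels for s in a] == [s.labels for s in b]


class TestSweepBin:
    def test_ranked_list_has_16_entries(self, planted_table):
        assert all(len(b.ranked) == 16 for b in planted_table.bins)

    def test_ranking_is_bic_ascending(self, planted_table):
        for b in planted_table.bins:
            bics = [rm.fit.bic for rm in b.ranked if rm.fit.converged]
            assert all(x <= y + 1e-9 for x, y in zip(bics, bics[1:]))

    def test_planted_matrix_recovered(self, planted_table):
        freqs = cn.inclusion_frequencies(planted_table)["per_matrix"]
        assert freqs["overall"].idxmax() == "S_adj"

    def test_iid_noise_prefers_null_on_sparse_networks(self, ring100):
        from culturenet.synthetic_data import ring_lattice_weights
        nets = {"ring": ring100, "wide": ring_lattice_weights(100, 8, label="wide")}
        rng = np.random.default_rng(55)
        nulls = 0
        reps = 30
        for rep in range(reps):
            y = rng.standard_normal(100)
            res = sweep_bin(y, nets, bin_index=rep)
            nulls += res.preferred.spec.name == "null"
        assert nulls > reps / 2  # majority, comfortably

    def test_dense_valued_matrix_overincluded_on_noise(self, small_world):
        """The known topology bias: on pure noise, the dense spatial-proximity
        affinity is selected far above its chance share — the phenomenon the
        diffusion bias study is designed to expose."""
        rng = np.random.default_rng(55)
        sp = 0
        reps = 30
        for rep in range(reps):
            y = rng.standard_normal(small_world.n)
            res = sweep_bin(y, small_world.networks, bin_index=rep)
            sp += "S_prox" in res.preferred.spec.labels
        assert sp > reps * 0.2


class TestBayesFactor:
    @pytest.mark.parametrize("delta,expected", [
        (3.53, 7.06), (1.74, 3.48), (2.22, 4.44), (3.56, 7.12),
        (2.64, 5.28), (2.13, 4.26), (3.48, 6.96), (0.0, 0.0),
    ])
    def test_doubling_convention(self, delta, expected):
        assert cn.bayes_factor(delta) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            cn.bayes_factor(-0.1)

    def test_interpretation_bands(self):
        assert bayes_factor_band(1.0) == "weak"
        assert bayes_factor_band(3.48) == "positive"
        assert bayes_factor_band(7.06) == "strong"


class TestInclusionFrequencies:
    def test_overall_is_preferred_plus_second(self, planted_table):
        f = cn.inclusion_frequencies(planted_table)["per_matrix"]
        assert (f["overall"] == f["preferred"] + f["second"]).all()

    def test_preferred_column_sums_to_bin_count(self, planted_table):
        per_spec = cn.inclusion_frequencies(planted_table)["per_spec"]
        assert per_spec["preferred"].sum() == len(planted_table.bins)
        assert per_spec["second"].sum() == len(planted_table.bins)

    def test_double_counting_when_in_both_top_models(self):
        # a matrix in preferred and 2nd-best of the same bin counts twice
        from culturenet.model_selection import BinResult, ModelSpec, RankedModel
        from culturenet.netautoreg import FitResult

        def fake(spec_labels, bic_val):
            fr = FitResult(beta=np.zeros(1), sigma2=1.0, rho=np.zeros(len(spec_labels)),
                           rho_se=np.zeros(len(spec_labels)), rho_p=np.zeros(len(spec_labels)),
                           loglik=0.0, bic=bic_val, n=10, k_params=2, converged=True,
                           labels=tuple(spec_labels))
            return RankedModel(spec=ModelSpec(tuple(spec_labels)), fit=fr)

        b = BinResult(bin_label="0", bin_index=0, n=10, ranked=[
            fake(("A",), 1.0), fake(("A", "B"), 2.0), fake((), 3.0)])
        table = SelectionTable(bins=[b], matrix_labels=("A", "B"))
        f = cn.inclusion_frequencies(table, ["A", "B"])["per_matrix"]
        assert f.loc["A", "overall"] == 2
        assert f.loc["B", "overall"] == 1


class TestMedianGaps:
    def test_single_bin_gaps_pass_through(self, planted_table):
        t = SelectionTable(bins=planted_table.bins[:1],
                           matrix_labels=planted_table.matrix_labels)
        g12, g13 = cn.median_bic_gaps(t)
        assert g12 == planted_table.bins[0].gap(1)
        assert g13 == planted_table.bins[0].gap(2)

    def test_gaps_nonnegative_and_ordered(self, planted_table):
        g12, g13 = cn.median_bic_gaps(planted_table)
        assert 0 <= g12 <= g13


class TestSignificanceCensus:
    def test_type_i_rate_near_alpha(self, ring100):
        rng = np.random.default_rng(2)
        reps = 200
        triples = [(str(i), rng.standard_normal(100), ring100) for i in range(reps)]
        census = cn.significance_census(triples, alpha=0.05)
        se = np.sqrt(0.05 * 0.95 / reps)
        assert census.n_tested == reps
        assert census.n_significant / reps < 0.05 + 3 * se + 0.02

    def test_power_with_planted_signal(self, ring100):
        triples = []
        for i in range(20):
            y = cn.sample_disturbance_outcome([ring100], [0.8], seed=300 + i)
            triples.append((str(i), y, ring100))
        census = cn.significance_census(triples, alpha=0.05)
        assert census.n_significant >= 16  # near-total power at rho = 0.8

    def test_empty_input_gives_zero_totals(self):
        census = cn.significance_census([], alpha=0.05)
        assert census.n_tested == 0 and census.n_significant == 0


class TestRhoSummary:
    def test_hand_computed_t(self):
        census = SignificanceCensus(matrix_label="A", alpha=0.05, n_significant=3,
                                    n_tested=10, significant_rhos=[0.12, 0.13, 0.14],
                                    significant_bins=["a", "b", "c"])
        s = cn.summarize_significant_rhos(census)
        assert s.mean == pytest.approx(0.13)
        assert s.df == 2
        # t = mean / (sd/sqrt(k)) = 0.13 / (0.01/sqrt(3)) = 22.516...
        from scipy import stats
        t = 0.13 / (0.01 / np.sqrt(3))
        assert s.t_pvalue == pytest.approx(2 * stats.t.sf(t, 2), rel=1e-6)
        half = stats.t.ppf(0.975, 2) * 0.01 / np.sqrt(3)
        assert s.ci_low == pytest.approx(0.13 - half)
        assert s.ci_high == pytest.approx(0.13 + half)

    def test_all_equal_values_flagged(self):
        census = SignificanceCensus("A", 0.05, 2, 5, [0.2, 0.2], ["a", "b"])
        s = cn.summarize_significant_rhos(census)
        assert s.flagged and s.ci_low == s.ci_high == 0.2

    def test_empty_census_flagged(self):
        census = SignificanceCensus("A", 0.05, 0, 5, [], [])
        s = cn.summarize_significant_rhos(census)
        assert s.flagged and s.df == -1 and np.isnan(s.t_pvalue)


class TestEvenOddRobustness:
    def _table_with_inclusions(self, planted_table, indices):
        bins = [planted_table.bins[i] for i in indices]
        for new_idx, b in enumerate(bins):
            b.bin_index = new_idx
        return SelectionTable(bins=bins, matrix_labels=planted_table.matrix_labels)

    def test_alternating_split_is_half(self, planted_table):
        r = cn.even_odd_robustness(planted_table, "S_adj")
        # S_adj is included in (almost) every bin by construction;
        # 8 bins alternate evenly
        if r["n_inclusions"] == 8:
            assert r["even_fraction"] == pytest.approx(0.5)
        assert r["even_fraction"] + r["odd_fraction"] == pytest.approx(1.0)

    def test_no_inclusions_flagged(self, planted_table):
        # a label never in any model
        r = cn.even_odd_robustness(
            SelectionTable(bins=planted_table.bins, matrix_labels=("ghost",)),
            "ghost")
        assert r["n_inclusions"] == 0 and np.isnan(r["even_fraction"])
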
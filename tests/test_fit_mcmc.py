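import math

import numpy as np
import pytest
from scipy import stats

from codonshift.codon_core import (
    CodonCountMatrix,
    ExpressionVector,
    ParameterSet,
    count_matrix,
)
from codonshift.fit_mcmc import (
    DicResult,
    McmcSettings,
    PosteriorSamples,
    compare_models,
    compute_dic,
    fit_full,
    fit_selection_only,
    posterior_interval,
)
from codonshift.region_partition import GroupingScheme, build_partitions
from codonshift.synthetic_data import (
    LabelSpec,
    SimulationConfig,
    random_parameters,
    simulate_genome,
)

FAST = McmcSettings(n_iterations=1500, thin=5)


class TestFitSelectionOnly:
    def test_null_recovery(self, table):
        # data simulated at delta_eta = 0: posterior means within 3 SD of 0
        truth = ParameterSet.zeros(table)
        uni = {f.family_id: 1.0 / 19 for f in table.families}
        config = SimulationConfig(
            n_genes=80, mean_length=120, min_length=60,
            labels=[LabelSpec("H", uni)], seed=21,
        )
        genome = simulate_genome(config, truth)
        counts = count_matrix(genome.sequences(), table=table)
        samples = fit_selection_only(
            counts, truth, genome.expression(), FAST, seed=22
        )
        for name in samples.param_names:
            col = samples.column(name)
            assert abs(col.mean()) < 3 * col.std(ddof=1) + 0.05

    def test_two_codon_conjugate_oracle(self, table):
        # phi = 1 everywhere: posterior concentrates at
        # -log(n2/n1) - dM2 for a two-codon family
        dm2 = 0.3
        n1, n2 = 3000, 1000
        params = ParameterSet.from_values(table, {"TGT": dm2}, {})
        counts_arr = np.zeros((1, table.n_codons), dtype=int)
        idx = table.codon_index()
        counts_arr[0, idx["TGC"]] = n1
        counts_arr[0, idx["TGT"]] = n2
        counts = CodonCountMatrix(table, ["g"], counts_arr)
        phis = ExpressionVector(["g"], np.array([1.0]))
        samples = fit_selection_only(
            counts, params, phis, McmcSettings(n_iterations=4000, thin=5), seed=23
        )
        expected = -math.log(n2 / n1) - dm2
        col = samples.column("TGT")
        assert abs(col.mean() - expected) < 4 * col.std(ddof=1)
        # all other families had zero counts -> prior-draw fallback + warning
        assert any("zero counts" in w for w in samples.warnings)
        prior_col = samples.column("GCC")
        assert prior_col.std(ddof=1) > 5  # prior sd is 10

    def test_gene_mismatch_rejected(self, table, truth_params):
        counts = count_matrix({"g": ["TGC"]}, table=table)
        phis = ExpressionVector(["other"], np.array([1.0]))
        with pytest.raises(ValueError, match="same genes"):
            fit_selection_only(counts, truth_params, phis, FAST, seed=1)

    def test_deterministic_under_seed(self, small_counts, truth_params,
                                      small_genome):
        phis = small_genome.expression()
        tiny = McmcSettings(n_iterations=200, thin=2)
        a = fit_selection_only(small_counts, truth_params, phis, tiny, seed=5)
        b = fit_selection_only(small_counts, truth_params, phis, tiny, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)


@pytest.fixture(scope="module")
def full_fit(table):
    params = random_parameters(table, 11, sd_selection=0.8)
    uni = {f.family_id: 1.0 / 19 for f in table.families}
    config = SimulationConfig(
        n_genes=250, mean_length=400, min_length=100,
        labels=[LabelSpec("H", uni)], sdlog=1.0, seed=31,
    )
    genome = simulate_genome(config, params)
    counts = count_matrix(genome.sequences(), table=table)
    samples = fit_full(
        counts, McmcSettings(n_iterations=2000, thin=5), seed=32
    )
    return genome, params, counts, samples


class TestFitFull:
    def test_phi_rank_correlation(self, full_fit):
        genome, _, counts, samples = full_fit
        means = samples.posterior_mean()
        phi_hat = np.array([means[f"phi:{g}"] for g in counts.gene_ids])
        rho = stats.spearmanr(phi_hat, genome.expression().phi).statistic
        assert rho >= 0.9

    def test_mean_phi_constraint_exact(self, full_fit):
        _, _, counts, samples = full_fit
        phi_cols = [samples.column(f"phi:{g}") for g in counts.gene_ids]
        means = np.array([c.mean() for c in phi_cols])
        assert abs(means.mean() - 1.0) < 1e-8

    def test_selection_recovered(self, full_fit):
        _, params, _, samples = full_fit
        means = samples.posterior_mean()
        de_hat = np.array(
            [means.get(f"deta:{c}", 0.0) for c in params.table.codons]
        )
        assert np.corrcoef(de_hat, params.delta_eta)[0, 1] > 0.9

    def test_identifiability_lost_without_phi_variation(self, table):
        # all phi equal: only dM + deta is identified, so deta goes wide
        params = random_parameters(table, 12, sd_selection=0.15)
        uni = {f.family_id: 1.0 / 19 for f in table.families}
        config = SimulationConfig(
            n_genes=40, mean_length=80, min_length=40, sdlog=0.0,
            labels=[LabelSpec("H", uni)], seed=33,
        )
        genome = simulate_genome(config, params)
        counts = count_matrix(genome.sequences(), table=table)
        samples = fit_full(
            counts, McmcSettings(n_iterations=2500, thin=5), seed=34
        )
        iv = posterior_interval(samples)
        widths = [
            iv[f"deta:{c}"][1] - iv[f"deta:{c}"][0]
            for c in table.codons
            if f"deta:{c}" in iv
        ]
        truth_spread = params.delta_eta.max() - params.delta_eta.min()
        assert np.mean(widths) > truth_spread

    def test_too_few_genes_rejected(self, table):
        counts = count_matrix({"g": ["TGC"]}, table=table)
        with pytest.raises(ValueError, match="at least 2 genes"):
            fit_full(counts, FAST, seed=1)


def _samples_with_deviance(deviances, loglik_at=None):
    n = len(deviances)
    return PosteriorSamples(
        param_names=["a"],
        draws=np.zeros((n, 1)),
        deviance=np.asarray(deviances, dtype=float),
        seed=0,
        settings=McmcSettings(),
        loglik_fn=loglik_at,
    )


class TestDic:
    def test_degenerate_posterior(self):
        s = _samples_with_deviance([8.0, 8.0], loglik_at=lambda v: -4.0)
        dic = compute_dic(s)
        assert dic.p_d == pytest.approx(0.0)
        assert dic.dic == pytest.approx(8.0)

    def test_hand_arithmetic(self):
        # deviances 10 and 14, deviance at mean params 9
        s = _samples_with_deviance([10.0, 14.0], loglik_at=lambda v: -4.5)
        dic = compute_dic(s)
        assert dic.d_bar == pytest.approx(12.0)
        assert dic.p_d == pytest.approx(3.0)
        assert dic.dic == pytest.approx(15.0)

    def test_pv_variant(self):
        s = _samples_with_deviance([10.0, 14.0], loglik_at=lambda v: -4.5)
        dic = compute_dic(s, variant="p_v")
        assert dic.p_d == pytest.approx(np.var([10, 14], ddof=1) / 2)

    def test_needs_two_draws(self):
        s = _samples_with_deviance([10.0], loglik_at=lambda v: -5.0)
        with pytest.raises(ValueError, match="at least 2"):
            compute_dic(s)

    def test_dic_additivity(self):
        a = DicResult(10.0, 8.0)
        b = DicResult(6.0, 5.0)
        combined = a + b
        assert combined.dic == pytest.approx(a.dic + b.dic)


class TestCompareModels:
    def test_single_model_delta_zero(self):
        df = compare_models([("m", DicResult(10.0, 9.0))])
        assert df["delta_dic"].iloc[0] == 0.0

    def test_sorted_ascending_nonnegative(self):
        df = compare_models(
            [("worse", DicResult(30.0, 25.0)), ("best", DicResult(12.0, 10.0))]
        )
        assert list(df["scheme"]) == ["best", "worse"]
        assert (df["delta_dic"] >= 0).all()
        assert df["support"].iloc[0] == "substantial"
        assert df["support"].iloc[1] == "disregarded"

    def test_separate_model_wins_under_genuine_difference(self, table):
        # two labels simulated with different selection: the separate
        # grouping attains the lower DIC
        params_a = random_parameters(table, 41)
        params_b = ParameterSet(table, params_a.delta_M, -params_a.delta_eta)
        uni = {f.family_id: 1.0 / 19 for f in table.families}
        specs = [
            LabelSpec("A", uni, mean_segment_length=10),
            LabelSpec("B", uni, mean_segment_length=10),
        ]
        config = SimulationConfig(
            n_genes=80, mean_length=160, min_length=80, labels=specs,
            flip_label="B", flip_fraction=1.0, seed=42,
        )
        genome = simulate_genome(config, params_a)
        phis = genome.expression()
        seqs, track = genome.sequences(), genome.label_track()
        sep = build_partitions(seqs, track, GroupingScheme.separate(["A", "B"]))
        mer = build_partitions(seqs, track, GroupingScheme.merged(["A", "B"]))
        dic_sep = None
        for counts in sep.group_counts.values():
            s = fit_selection_only(counts, params_a, phis, FAST, seed=43)
            d = compute_dic(s)
            dic_sep = d if dic_sep is None else dic_sep + d
        s = fit_selection_only(
            mer.group_counts["all"], params_a, phis, FAST, seed=44
        )
        dic_mer = compute_dic(s)
        df = compare_models([("separate", dic_sep), ("merged", dic_mer)])
        assert df["scheme"].iloc[0] == "separate"
        assert df["delta_dic"].iloc[1] > 10


class TestPosteriorInterval:
    def test_constant_draws(self):
        s = _samples_with_deviance([0.0, 0.0])
        s.draws = np.full((2, 1), 3.25)
        assert posterior_interval(s)["a"] == (3.25, 3.25)

    def test_quantile_oracle(self):
        s = PosteriorSamples(
            param_names=["a"],
            draws=np.arange(1.0, 101.0).reshape(-1, 1),
            deviance=np.zeros(100),
            seed=0,
            settings=McmcSettings(),
        )
        lo, hi = posterior_interval(s, 0.95)["a"]
        assert lo == pytest.approx(np.quantile(np.arange(1.0, 101.0), 0.025))
        assert hi == pytest.approx(np.quantile(np.arange(1.0, 101.0), 0.975))

    def test_widens_with_level(self):
        rng = np.random.default_rng(1)
        s = PosteriorSamples(
            param_names=["a"],
            draws=rng.standard_normal((500, 1)),
            deviance=np.zeros(500),
            seed=0,
            settings=McmcSettings(),
        )
        w50 = np.diff(posterior_interval(s, 0.5)["a"])[0]
        w95 = np.diff(posterior_interval(s, 0.95)["a"])[0]
        assert w95 > w50

    def test_invalid_level(self):
        s = _samples_with_deviance([0.0, 0.0])
        with pytest.raises(ValueError):
            posterior_interval(s, 1.0)
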
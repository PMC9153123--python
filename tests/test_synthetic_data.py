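import numpy as np
import pytest
from scipy import stats

from codonshift.codon_core import ParameterSet, codon_probabilities
from codonshift.synthetic_data import (
    LabelSpec,
    SimulationConfig,
    flip_selection_sites,
    simulate_annotations,
    simulate_codons,
    simulate_expression,
    simulate_genome,
    simulate_null_replicates,
)


class TestSimulateExpression:
    def test_sdlog_zero_gives_unit_phi(self):
        ev = simulate_expression(10, 0.0, seed=1)
        np.testing.assert_allclose(ev.phi, 1.0)

    def test_mean_one_at_large_n(self):
        # E[phi]=1 by the lognormal moment formula; 3 SE band at n=10,000
        ev = simulate_expression(10_000, 1.0, seed=2)
        se = np.sqrt((np.e * (np.e - 1))) / np.sqrt(10_000)
        assert abs(ev.phi.mean() - 1.0) < 3 * se

    def test_deterministic_under_seed(self):
        a = simulate_expression(50, 1.0, seed=3)
        b = simulate_expression(50, 1.0, seed=3)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_expression(0, 1.0, seed=1)
        with pytest.raises(ValueError):
            simulate_expression(5, -0.1, seed=1)


class TestLabelSpec:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LabelSpec("H", {"A": 0.5, "G": 0.2})


class TestSimulateAnnotations:
    def test_single_label_constant(self, uniform_composition):
        config = SimulationConfig(
            n_genes=5, mean_length=100, min_length=50,
            labels=[LabelSpec("H", uniform_composition)], seed=4,
        )
        _, fam_seqs, label_seqs = simulate_annotations(config)
        for labels in label_seqs:
            assert set(labels) == {"H"}

    def test_single_label_uniform_frequencies(self, uniform_composition):
        config = SimulationConfig(
            n_genes=50, mean_length=200, min_length=100,
            labels=[LabelSpec("H", uniform_composition)], seed=5,
        )
        _, fam_seqs, _ = simulate_annotations(config)
        flat = [f for seq in fam_seqs for f in seq]
        counts = np.array([flat.count(k) for k in uniform_composition])
        p = stats.chisquare(counts).pvalue
        assert p > 1e-4

    def test_disjoint_alphabets_recoverable(self):
        specs = [
            LabelSpec("X", {"A": 1.0}, mean_segment_length=5),
            LabelSpec("Y", {"G": 1.0}, mean_segment_length=5),
        ]
        config = SimulationConfig(
            n_genes=10, mean_length=80, min_length=40, labels=specs, seed=6
        )
        _, fam_seqs, label_seqs = simulate_annotations(config)
        for fams, labels in zip(fam_seqs, label_seqs):
            for f, l in zip(fams, labels):
                assert (f, l) in {("A", "X"), ("G", "Y")}

    def test_min_segment_length_respected(self, uniform_composition):
        specs = [
            LabelSpec("H", uniform_composition, mean_segment_length=8,
                      min_segment_length=4),
            LabelSpec("C", uniform_composition, mean_segment_length=8,
                      min_segment_length=4),
        ]
        config = SimulationConfig(
            n_genes=20, mean_length=150, min_length=80, labels=specs, seed=7
        )
        _, _, label_seqs = simulate_annotations(config)
        for labels in label_seqs:
            runs = []
            start = 0
            for i in range(1, len(labels) + 1):
                if i == len(labels) or labels[i] != labels[start]:
                    runs.append(i - start)
                    start = i
            # only the final (truncated) run may undershoot the minimum
            assert all(r >= 4 for r in runs[:-1])


class TestFlipSelectionSites:
    def test_zero_fraction_empty(self):
        masks = flip_selection_sites([["B"] * 10], 0.0, "B", seed=1)
        assert not masks[0].any()

    def test_full_fraction_flags_all_region_sites(self):
        labels = [["A"] * 5 + ["B"] * 5]
        masks = flip_selection_sites(labels, 1.0, "B", seed=1)
        assert masks[0][5:].all() and not masks[0][:5].any()

    def test_round_half_to_even_on_101_sites(self):
        labels = [["B"] * 101]
        masks = flip_selection_sites(labels, 0.5, "B", seed=2)
        # round(50.5) -> 50 under round-half-to-even
        assert masks[0].sum() == 50

    def test_exact_count(self):
        labels = [["B"] * 40, ["A"] * 10 + ["B"] * 60]
        masks = flip_selection_sites(labels, 0.1, "B", seed=3)
        assert sum(m.sum() for m in masks) == 10
        assert not masks[1][:10].any()


class TestSimulateCodons:
    def _two_codon_setup(self, table):
        # one strongly favored codon in every family
        de = {}
        for fam in table.families:
            for j, c in enumerate(fam.codons):
                if j != fam.reference_index:
                    de[c] = 10.0
        return ParameterSet.from_values(table, {}, de)

    def test_strong_selection_fixes_favored_codon(self, table):
        params = self._two_codon_setup(table)
        n = 2000
        from codonshift.codon_core import ExpressionVector
        phis = ExpressionVector(["g"], np.array([5.0]))
        genome = simulate_codons(
            ["g"], [["C"] * n], [["H"] * n], params,
            [np.zeros(n, dtype=bool)], phis, seed=8,
        )
        freq = genome.genes[0].codons.count("TGC") / n
        assert freq > 0.99

    def test_translation_preserved(self, small_genome, table, truth_params):
        fam_of = table.family_of()
        for gene in small_genome.genes:
            for codon in gene.codons:
                assert codon in fam_of or codon in ("ATG", "TGG")

    def test_frequencies_match_model(self, table, truth_params):
        # chi-square goodness of fit on a 1e5-site single-family simulation
        n = 100_000
        from codonshift.codon_core import ExpressionVector
        phis = ExpressionVector(["g"], np.array([1.3]))
        genome = simulate_codons(
            ["g"], [["L"] * n], [["H"] * n], truth_params,
            [np.zeros(n, dtype=bool)], phis, seed=9,
        )
        fam = table.family("L")
        expected = codon_probabilities(fam, truth_params, 1.3) * n
        observed = np.array(
            [genome.genes[0].codons.count(c) for c in fam.codons]
        )
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_full_flip_mirrors_negated_selection(self, table, truth_params):
        n = 50_000
        from codonshift.codon_core import ExpressionVector
        phis = ExpressionVector(["g"], np.array([1.0]))
        flipped = simulate_codons(
            ["g"], [["A"] * n], [["H"] * n], truth_params,
            [np.ones(n, dtype=bool)], phis, seed=10,
        )
        neg = ParameterSet(table, truth_params.delta_M, -truth_params.delta_eta)
        fam = table.family("A")
        expected = codon_probabilities(fam, neg, 1.0) * n
        observed = np.array([flipped.genes[0].codons.count(c) for c in fam.codons])
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_unknown_family_rejected(self, truth_params):
        from codonshift.codon_core import ExpressionVector
        phis = ExpressionVector(["g"], np.array([1.0]))
        with pytest.raises(ValueError, match="unknown amino acid"):
            simulate_codons(
                ["g"], [["?"]], [["H"]], truth_params,
                [np.zeros(1, dtype=bool)], phis, seed=1,
            )


class TestNullReplicates:
    def test_single_replicate_reproduces_simulate_codons(
        self, table, truth_params, uniform_composition
    ):
        config = SimulationConfig(
            n_genes=5, mean_length=60, min_length=30,
            labels=[LabelSpec("H", uniform_composition)], seed=11,
        )
        gene_ids, fam_seqs, label_seqs = simulate_annotations(config)
        phis = simulate_expression(5, 1.0, seed=12)
        reps = simulate_null_replicates(
            gene_ids, fam_seqs, label_seqs, truth_params, phis, 1, seed=13
        )
        child = int(np.random.SeedSequence(13).generate_state(1)[0])
        direct = simulate_codons(
            gene_ids, fam_seqs, label_seqs, truth_params,
            [np.zeros(len(s), dtype=bool) for s in fam_seqs], phis, child,
        )
        assert reps[0].sequences() == direct.sequences()

    def test_reproducible_set(self, table, truth_params, uniform_composition):
        config = SimulationConfig(
            n_genes=4, mean_length=50, min_length=30,
            labels=[LabelSpec("H", uniform_composition)], seed=14,
        )
        gene_ids, fam_seqs, label_seqs = simulate_annotations(config)
        phis = simulate_expression(4, 0.5, seed=15)
        a = simulate_null_replicates(
            gene_ids, fam_seqs, label_seqs, truth_params, phis, 3, seed=16
        )
        b = simulate_null_replicates(
            gene_ids, fam_seqs, label_seqs, truth_params, phis, 3, seed=16
        )
        for ga, gb in zip(a, b):
            assert ga.sequences() == gb.sequences()
        # replicates differ from each other
        assert a[0].sequences() != a[1].sequences()

    def test_replicate_variance_near_binomial(self, table, truth_params):
        # per-codon frequency variance across replicates within 3x binomial
        n_sites, n_reps = 4000, 24
        from codonshift.codon_core import ExpressionVector
        phis = ExpressionVector(["g"], np.array([1.0]))
        reps = simulate_null_replicates(
            ["g"], [["C"] * n_sites], [["H"] * n_sites],
            truth_params, phis, n_reps, seed=17,
        )
        p = codon_probabilities(table.family("C"), truth_params, 1.0)[0]
        freqs = np.array(
            [r.genes[0].codons.count("TGC") / n_sites for r in reps]
        )
        expected_var = p * (1 - p) / n_sites
        assert expected_var / 3 < freqs.var(ddof=1) < expected_var * 3


class TestSimulateGenome:
    def test_translation_round_trip(self, small_genome, truth_params):
        fam_of = truth_params.table.family_of()
        letter = {
            **{fid: ("S" if fid in ("S2", "S4") else fid) for fid in fam_of.values()},
        }
        for gene in small_genome.genes:
            aa = gene.translate()
            assert len(aa) == len(gene.codons)
            assert "*" not in aa

    def test_flip_flags_confined_to_region(self, table, truth_params,
                                           uniform_composition):
        specs = [
            LabelSpec("A", uniform_composition, mean_segment_length=8),
            LabelSpec("B", uniform_composition, mean_segment_length=8),
        ]
        config = SimulationConfig(
            n_genes=10, mean_length=100, min_length=50, labels=specs,
            flip_label="B", flip_fraction=0.5, seed=18,
        )
        genome = simulate_genome(config, truth_params)
        for gene in genome.genes:
            for label, flp in zip(gene.labels, gene.flipped):
                if flp:
                    assert label == "B"

    def test_annotation_tsv_round_trip(self, small_genome, tmp_path):
        from codonshift.workflow_io import read_annotation_tsv
        path = tmp_path / "ann.tsv"
        small_genome.write_annotation_tsv(path)
        track, flips = read_annotation_tsv(path)
        assert track == small_genome.label_track()
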
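"""Coalescent simulator calibration, sequence evolution and the filter cascade."""

import numpy as np
import pytest

from raddisc.io_formats import Alignment, alignment_to_snps
from raddisc.synthetic_data import (
    AdmixturePulse,
    ConfigError,
    GeneTree,
    SimulatedDataset,
    SimulationConfig,
    SpeciesModel,
    apply_rad_missingness,
    evolve_sequences,
    filter_cascade,
    filter_min_samples,
    five_clade_model,
    generate_dataset,
    simulate_gene_trees,
    summarize,
)


def single_pop_model(n: int) -> SpeciesModel:
    return SpeciesModel.from_newick("(A:1,B:1)r;", {"A": n, "B": 0})


class TestCoalescent:
    def test_pairwise_tmrca_is_one(self):
        """Within-population pairwise TMRCA has mean 1 coalescent unit."""
        cfg = SimulationConfig(single_pop_model(2), n_loci=2000, locus_length=1,
                               mu=0.0, seed=7)
        t = np.array([gt.tmrca("A_0", "A_1") for gt in simulate_gene_trees(cfg)])
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert abs(t.mean() - 1.0) < 3 * se

    @pytest.mark.parametrize("T", [0.1, 1.0, 3.0])
    def test_four_taxon_discordance_matches_closed_form(self, T):
        """P(discordant gene tree) = (2/3) exp(-T) for internal branch T."""
        nw = f"(((A:1,B:1)ab:{T},C:{1 + T})abc:1,D:{2 + T})r;"
        model = SpeciesModel.from_newick(nw, {t: 1 for t in "ABCD"})
        n = 3000
        cfg = SimulationConfig(model, n_loci=n, locus_length=1, mu=0.0, seed=13)
        disc = 0
        for gt in simulate_gene_trees(cfg):
            tab = gt.tmrca("A_0", "B_0")
            if min(tab, gt.tmrca("A_0", "C_0"), gt.tmrca("B_0", "C_0")) != tab:
                disc += 1
        p = (2 / 3) * np.exp(-T)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(disc / n - p) < 4 * se

    def test_full_strength_pulse_moves_all_lineages(self):
        """fraction=1 reroutes every recipient lineage into the donor."""
        nw = "(A:8,B:8)r;"
        model = SpeciesModel.from_newick(nw, {"A": 1, "B": 1})
        pulse = AdmixturePulse(donor="A", recipient="B", time=0.5, fraction=1.0)
        cfg = SimulationConfig(model, [pulse], n_loci=300, locus_length=1,
                               mu=0.0, seed=5)
        t = np.array([gt.tmrca("A_0", "B_0") for gt in simulate_gene_trees(cfg)])
        # both lineages sit in pop A from t=0.5; all coalesce before the split
        assert np.all(t < 8.0)
        assert abs(t.mean() - 1.5) < 0.25  # 0.5 + Exp(1), se ~ 1/sqrt(300)

    def test_pulse_outside_branch_interval_rejected(self):
        model = five_clade_model(2, 1)
        with pytest.raises(ConfigError, match="interval"):
            SimulationConfig(
                model,
                [AdmixturePulse(donor="p34", recipient="II", time=0.1, fraction=0.5)],
                seed=0,
            )

    def test_unknown_branch_rejected(self):
        model = five_clade_model(2, 1)
        with pytest.raises(ConfigError, match="unknown branch"):
            SimulationConfig(
                model,
                [AdmixturePulse(donor="nope", recipient="II", time=1.2, fraction=0.5)],
                seed=0,
            )

    def test_matches_msprime_oracle(self):
        """Cross-check gene-tree discordance against an msprime simulation."""
        import msprime

        T = 0.8
        nw = f"(((A:1,B:1)ab:{T},C:{1 + T})abc:1,D:{2 + T})r;"
        model = SpeciesModel.from_newick(nw, {t: 1 for t in "ABCD"})
        n = 2000
        cfg = SimulationConfig(model, n_loci=n, locus_length=1, mu=0.0, seed=29)
        mine = 0
        for gt in simulate_gene_trees(cfg):
            tab = gt.tmrca("A_0", "B_0")
            if min(tab, gt.tmrca("A_0", "C_0"), gt.tmrca("B_0", "C_0")) != tab:
                mine += 1

        # same demography in msprime: haploid lineages in a population of
        # size 1 coalesce at rate 1 per pair, so msprime time units equal
        # coalescent units
        dem = msprime.Demography()
        for name in ("A", "B", "C", "D", "AB", "ABC", "R"):
            dem.add_population(name=name, initial_size=1.0)
        dem.add_population_split(time=1.0, derived=["A", "B"], ancestral="AB")
        dem.add_population_split(time=1.0 + T, derived=["AB", "C"], ancestral="ABC")
        dem.add_population_split(time=2.0 + T, derived=["ABC", "D"], ancestral="R")
        other = 0
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1, "D": 1}, demography=dem, ploidy=1,
            num_replicates=n, random_seed=29,
        )
        for ts in reps:
            tr = ts.first()
            tab = tr.tmrca(0, 1)
            if min(tab, tr.tmrca(0, 2), tr.tmrca(1, 2)) != tab:
                other += 1
        p1, p2 = mine / n, other / n
        se = np.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n)
        assert abs(p1 - p2) < 4 * se


class TestEvolveSequences:
    def _pair_tree(self, t: float) -> GeneTree:
        return GeneTree(np.array([2, 2, -1]), np.array([0.0, 0.0, t]), ["x", "y"])

    def test_zero_rate_identical_sequences(self):
        seqs = evolve_sequences(self._pair_tree(1.0), 200, 0.0, 3)
        assert np.array_equal(seqs[0], seqs[1])

    def test_mismatch_matches_jc_closed_form(self):
        t, mu, L = 1.0, 0.3, 30000
        seqs = evolve_sequences(self._pair_tree(t), L, mu, 11)
        d = 2 * t * mu  # path length between the two leaves
        p = 0.75 * (1 - np.exp(-4 * d / 3))
        obs = np.mean(seqs[0] != seqs[1])
        assert abs(obs - p) < 4 * np.sqrt(p * (1 - p) / L)

    def test_variable_column_count_near_expectation(self):
        # low-rate limit: expected variable fraction ~ mu * tree length,
        # with the exact JC correction for multiple hits
        t, mu, L = 1.0, 0.002, 200000
        seqs = evolve_sequences(self._pair_tree(t), L, mu, 19)
        p = 0.75 * (1 - np.exp(-4 * (2 * t * mu) / 3))
        assert p == pytest.approx(mu * 2 * t, rel=0.01)  # first-order regime
        obs = np.mean(seqs[0] != seqs[1])
        assert abs(obs - p) < 4 * np.sqrt(p * (1 - p) / L)

    def test_negative_branch_rejected(self):
        bad = GeneTree(np.array([2, 2, -1]), np.array([0.0, 0.5, 0.2]), ["x", "y"])
        with pytest.raises(ValueError, match="negative"):
            evolve_sequences(bad, 10, 0.1, 0)


def toy_dataset(n_samples=5, n_loci=3, length=4) -> SimulatedDataset:
    seqs = np.array(
        [list("ACGT" * n_loci) for _ in range(n_samples)], dtype="S1"
    )
    rng = np.random.default_rng(0)
    mut = rng.random(seqs.shape) < 0.3
    seqs[mut] = b"T"
    bounds = [(k * length, (k + 1) * length) for k in range(n_loci)]
    aln = Alignment([f"s{i}" for i in range(n_samples)], seqs, bounds)
    return SimulatedDataset(aln, alignment_to_snps(aln), {})


class TestMissingnessAndFilter:
    def test_zero_dropout_is_identity(self):
        ds = toy_dataset()
        out = apply_rad_missingness(ds, 0.0, seed=1)
        assert out.alignment == ds.alignment

    def test_full_dropout_erases_everything(self):
        out = apply_rad_missingness(toy_dataset(), 1.0, seed=1)
        assert np.all(out.alignment.seqs == b"N")
        assert out.snps.n_sites == 0

    def test_mean_retained_samples_binomial(self):
        n_samples, n_loci, rate = 20, 1000, 0.3
        seqs = np.full((n_samples, n_loci), b"A", dtype="S1")
        seqs[0, :] = b"C"  # keep some variation
        aln = Alignment(
            [f"s{i}" for i in range(n_samples)], seqs,
            [(k, k + 1) for k in range(n_loci)],
        )
        ds = SimulatedDataset(aln, alignment_to_snps(aln), {})
        out = apply_rad_missingness(ds, rate, seed=9)
        mean_retained = out.retained_per_locus().mean()
        se = np.sqrt(n_samples * rate * (1 - rate) / n_loci)
        assert abs(mean_retained - 14.0) < 3 * se

    def test_min_zero_is_identity(self):
        ds = toy_dataset()
        out = filter_min_samples(ds, 0)
        assert out.alignment == ds.alignment

    def test_toy_counts(self):
        # 3 loci covered by {5, 3, 1} of 5 samples
        ds = toy_dataset(n_samples=5, n_loci=3)
        seqs = ds.alignment.seqs.copy()
        seqs[3:, 4:8] = b"N"   # locus 1: 3 covered
        seqs[1:, 8:12] = b"N"  # locus 2: 1 covered
        aln = Alignment(ds.alignment.sample_ids, seqs, ds.alignment.locus_bounds)
        ds2 = SimulatedDataset(aln, alignment_to_snps(aln), {})
        assert summarize(filter_min_samples(ds2, 3))["n_loci"] == 2
        assert summarize(filter_min_samples(ds2, 4))["n_loci"] == 1

    def test_cascade_monotone(self):
        model = five_clade_model(3, 2)
        cfg = SimulationConfig(model, n_loci=120, locus_length=40, mu=0.005,
                               dropout=0.35, seed=17)
        ds = generate_dataset(cfg)
        table = filter_cascade(ds, [0, 4, 8, 12, 16])
        for col in ("n_loci", "total_length", "n_snps"):
            assert (np.diff(table[col]) <= 0).all()


class TestGenerateDataset:
    def test_same_seed_identical(self):
        model = five_clade_model(2, 1)
        cfg = SimulationConfig(model, n_loci=30, locus_length=32, mu=0.005,
                               dropout=0.2, seed=77)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert np.array_equal(a.alignment.seqs, b.alignment.seqs)
        assert a.snps == b.snps
        assert a.truth == b.truth

    def test_truth_records_pulse_verbatim(self):
        model = five_clade_model(2, 1)
        pulse = AdmixturePulse(donor="III", recipient="II", time=0.5, fraction=0.3)
        cfg = SimulationConfig(model, [pulse], n_loci=5, locus_length=16,
                               mu=0.01, seed=1)
        ds = generate_dataset(cfg)
        assert ds.truth["pulses"] == [
            {"donor": "III", "recipient": "II", "time": 0.5, "fraction": 0.3}
        ]
        assert len(ds.truth["gene_trees"]) == 5

    def test_snps_derivable_from_alignment(self):
        model = five_clade_model(2, 1)
        cfg = SimulationConfig(model, n_loci=40, locus_length=32, mu=0.005,
                               dropout=0.3, seed=23)
        ds = generate_dataset(cfg)
        assert alignment_to_snps(ds.alignment) == ds.snps
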
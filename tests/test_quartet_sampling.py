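"""Branch partitions, quartet resolution and the QC/QD/QI/QF scores."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raddisc.io_formats import Alignment, read_newick
from raddisc.quartet_sampling import (
    QSConfig,
    QuartetReplicate,
    branch_and_taxon_scores,
    branch_partitions,
    draw_quartet,
    internal_branches,
    overlap_matrix,
    resolve_quartet,
    run_quartet_sampling,
)
from raddisc.synthetic_data import SimulationConfig, five_clade_model, generate_dataset


def _aln(rows: dict[str, str], bounds=None) -> Alignment:
    return Alignment(
        list(rows), np.array([list(s) for s in rows.values()], dtype="S1"), bounds
    )


class TestBranchPartitions:
    def test_five_leaf_tree(self):
        tree = read_newick("((a,b),(c,d),o);")
        parts = branch_partitions(tree)
        assert len(parts) == 2
        sizes = sorted(sorted(len(s) for s in p) for p in parts)
        assert all(sum(sz) == 5 for sz in sizes)
        flat = {frozenset(s) for p in parts for s in p}
        assert frozenset({"a"}) in flat and frozenset({"c", "d"}) in flat

    def test_balanced_eight_leaf_central_branch(self):
        tree = read_newick("(((a,b),(c,d)),((e,f),(g,h)));")
        parts = branch_partitions(tree)
        central = [p for p in parts if all(len(s) == 2 for s in p)]
        assert len(central) == 1
        assert set(map(frozenset, central[0])) == {
            frozenset({"a", "b"}), frozenset({"c", "d"}),
            frozenset({"e", "f"}), frozenset({"g", "h"}),
        }

    def test_graph_cut_oracle_random_trees(self):
        """Subsets equal connected components after deleting the branch."""
        import networkx as nx

        rng = np.random.default_rng(8)
        for _ in range(5):
            labels = [f"t{i}" for i in range(12)]
            clauses = list(labels)
            while len(clauses) > 1:
                i, j = sorted(rng.choice(len(clauses), 2, replace=False))
                b = clauses.pop(j)
                a = clauses.pop(i)
                clauses.append(f"({a},{b})")
            tree = read_newick(clauses[0] + ";")

            # oracle graph: unrooted adjacency over nodes
            g = nx.Graph()
            node_id = {}
            for k, nd in enumerate(tree.preorder_node_iter()):
                node_id[id(nd)] = k
                if nd.parent_node is not None:
                    g.add_edge(node_id[id(nd.parent_node)], k)
            root = node_id[id(tree.seed_node)]
            if g.degree[root] == 2:
                a, b = list(g.neighbors(root))
                g.remove_node(root)
                g.add_edge(a, b)
            leaves = {
                node_id[id(nd)]: nd.taxon.label for nd in tree.leaf_node_iter()
            }

            for edge in internal_branches(tree):
                got = set(map(frozenset, branch_partitions(tree, edge)))
                h = g.copy()
                u, v = edge
                h.remove_node(u)
                h.remove_node(v)
                want = {
                    frozenset(leaves[n] for n in comp if n in leaves)
                    for comp in nx.connected_components(h)
                }
                assert got == want

    def test_non_internal_branch_rejected(self):
        tree = read_newick("((a,b),(c,d),o);")
        with pytest.raises(ValueError, match="internal"):
            branch_partitions(tree, (97, 98))


class TestDrawQuartet:
    def test_complete_alignment_always_accepted(self):
        aln = _aln({t: "ACGTACGT" for t in "abcd"})
        ov = overlap_matrix(aln)
        rng = np.random.default_rng(0)
        cfg = QSConfig(n_replicates=1, min_overlap=0)
        for _ in range(10):
            assert draw_quartet([["a"], ["b"], ["c"], ["d"]], ov, cfg, rng) is not None

    def test_all_missing_taxon_always_fails(self):
        rows = {t: "ACGTACGT" for t in "abc"}
        rows["z"] = "NNNNNNNN"
        ov = overlap_matrix(_aln(rows))
        rng = np.random.default_rng(0)
        cfg = QSConfig(n_replicates=1, min_overlap=1, max_attempts=20)
        assert draw_quartet([["a"], ["b"], ["c"], ["z"]], ov, cfg, rng) is None

    def test_empty_subset_is_error(self):
        ov = overlap_matrix(_aln({t: "ACGT" for t in "abcd"}))
        with pytest.raises(ValueError, match="empty"):
            draw_quartet([["a"], [], ["c"], ["d"]], ov, QSConfig(), np.random.default_rng(0))

    def test_acceptance_rate_tracks_overlap_fraction(self):
        # 2 taxa per subset; one taxon of subset 0 overlaps nobody
        rows = {"a1": "ACGTACGT", "a2": "NNNNNNNN", "b": "ACGTACGT",
                "c": "ACGTACGT", "d": "ACGTACGT"}
        ov = overlap_matrix(_aln(rows))
        rng = np.random.default_rng(4)
        cfg = QSConfig(n_replicates=1, min_overlap=1, max_attempts=1)
        hits = sum(
            draw_quartet([["a1", "a2"], ["b"], ["c"], ["d"]], ov, cfg, rng) is not None
            for _ in range(2000)
        )
        assert abs(hits / 2000 - 0.5) < 0.05  # single-attempt acceptance = P(draw a1)


class TestResolveQuartet:
    def test_identical_sequences_uninformative(self):
        cols = np.zeros((4, 50), dtype=np.int8)
        outcome, delta = resolve_quartet(cols)
        assert outcome == "uninformative"
        assert delta == pytest.approx(0.0, abs=1e-6)

    def test_clean_synapomorphies_resolve_concordant(self):
        rng = np.random.default_rng(2)
        cols = np.zeros((4, 1000), dtype=np.int8)
        syn = rng.integers(1, 4, size=30)
        cols[2, :30] = syn
        cols[3, :30] = syn
        out_ml, d_ml = resolve_quartet(cols)
        out_pars, d_pars = resolve_quartet(cols, QSConfig(engine="parsimony"))
        assert out_ml == out_pars == "concordant"
        assert d_ml > 2.0 and d_pars == 30

    def test_balanced_conflict_is_uninformative(self):
        cols = np.zeros((4, 400), dtype=np.int8)
        cols[0, :20] = cols[1, :20] = 1  # 20 x AABB
        cols[0, 20:40] = cols[2, 20:40] = 1  # 20 x ABAB
        outcome, delta = resolve_quartet(cols)
        assert outcome == "uninformative"
        assert delta < 1e-3

    def test_missing_columns_ignored(self):
        cols = np.full((4, 10), 4, dtype=np.int8)
        with pytest.raises(ValueError, match="non-missing"):
            resolve_quartet(cols)

    def test_byte_input_equivalent_to_codes(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 4, size=(4, 200)).astype(np.int8)
        bases = np.array([b"A", b"C", b"G", b"T"])[codes]
        assert resolve_quartet(codes) == resolve_quartet(bases.astype("S1"))


def reps_from_tallies(t0, t1, t2, unin=0):
    taxa = ("w", "x", "y", "z")
    reps = []
    for outcome, n in (
        ("concordant", t0), ("discordant-1", t1), ("discordant-2", t2),
        ("uninformative", unin),
    ):
        reps.extend(QuartetReplicate(taxa, outcome, 5.0) for _ in range(n))
    return reps


class TestScores:
    def test_all_concordant_gives_qc_one_qd_dash(self):
        b, _ = branch_and_taxon_scores(reps_from_tallies(40, 0, 0))
        assert b.qc == pytest.approx(1.0)
        assert b.qd is None
        assert b.label().startswith("1/-/")

    def test_uniform_thirds(self):
        b, _ = branch_and_taxon_scores(reps_from_tallies(20, 20, 20))
        assert b.qc == pytest.approx(0.0, abs=1e-12)
        assert b.qd == pytest.approx(1.0)

    def test_full_counter_support(self):
        b, _ = branch_and_taxon_scores(reps_from_tallies(0, 30, 0))
        assert b.qc == pytest.approx(-1.0)
        assert b.qd == pytest.approx(0.0)

    def test_skewed_mixture_matches_arithmetic_oracle(self):
        t0, t1, t2 = 150, 75, 25
        b, _ = branch_and_taxon_scores(reps_from_tallies(t0, t1, t2))
        s = t0 + t1 + t2
        ent = sum((t / s) * math.log(t / s, 3) for t in (t0, t1, t2))
        assert b.qc == pytest.approx(1 + ent)
        assert b.qd == pytest.approx(1 - abs(t1 - t2) / (t1 + t2))
        assert b.qi == pytest.approx(1.0)

    def test_qi_counts_informative_fraction(self):
        b, _ = branch_and_taxon_scores(reps_from_tallies(10, 5, 5, unin=20))
        assert b.qi == pytest.approx(0.5)

    def test_qf_bookkeeping_conservation(self):
        reps = reps_from_tallies(12, 5, 3, unin=4)
        _, taxa = branch_and_taxon_scores(reps)
        lhs = sum(taxa.qf[t] * taxa.informative[t] for t in taxa.qf)
        assert lhs == pytest.approx(4 * 12)  # each concordant rep holds 4 taxa

    @settings(derandomize=True, max_examples=150)
    @given(st.integers(0, 300), st.integers(0, 300), st.integers(0, 300),
           st.integers(0, 100))
    def test_score_ranges_and_qd_extremes(self, t0, t1, t2, unin):
        """QC in [-1,1]; QD in [0,1], equal to 1 iff t1 == t2 (when defined)."""
        b, _ = branch_and_taxon_scores(reps_from_tallies(t0, t1, t2, unin))
        if b.qc is not None:
            assert -1.0 <= b.qc <= 1.0 + 1e-12
            if t1 == t2 == 0 and t0 > 0:
                assert b.qc == pytest.approx(1.0)
        if b.qd is not None:
            assert 0.0 <= b.qd <= 1.0
            assert (b.qd == 1.0) == (t1 == t2)


@pytest.fixture(scope="module")
def small_run():
    model = five_clade_model(2, 1)
    cfg = SimulationConfig(model, n_loci=80, locus_length=64, mu=0.01,
                           dropout=0.2, seed=31)
    ds = generate_dataset(cfg)
    names = ds.alignment.sample_ids

    def tip(t):
        xs = [n for n in names if n.startswith(t + "_")]
        return f"({xs[0]},{xs[1]})"

    tree = read_newick(
        f"(((({tip('I')},{tip('II')}),({tip('III')},{tip('IV')})),{tip('V')}),OUT_0);"
    )
    qs_cfg = QSConfig(30, min_overlap=100, seed=5)
    return ds, tree, qs_cfg


class TestRunQuartetSampling:
    def test_deterministic_for_fixed_seed(self, small_run):
        ds, tree, cfg = small_run
        a = run_quartet_sampling(ds.alignment, tree, cfg)
        b = run_quartet_sampling(ds.alignment, tree, cfg)
        assert a.branch_table().equals(b.branch_table())
        assert a.taxon_table().equals(b.taxon_table())

    def test_scores_within_bounds(self, small_run):
        ds, tree, cfg = small_run
        res = run_quartet_sampling(ds.alignment, tree, cfg)
        for sc in res.branch_scores.values():
            if sc.qc is not None:
                assert -1.0 <= sc.qc <= 1.0
            if sc.qd is not None:
                assert 0.0 <= sc.qd <= 1.0
            if sc.qi is not None:
                assert 0.0 <= sc.qi <= 1.0
        assert all(0.0 <= v <= 1.0 for v in res.taxon_scores.qf.values())

    def test_annotated_tree_carries_labels(self, small_run, tmp_path):
        from raddisc.io_formats import write_annotated_newick

        ds, tree, cfg = small_run
        res = run_quartet_sampling(ds.alignment, tree, cfg)
        write_annotated_newick(res.tree, tmp_path / "t.nwk")
        text = (tmp_path / "t.nwk").read_text()
        assert "/" in text  # QC/QD/QI labels present

    def test_too_few_taxa_rejected(self):
        aln = _aln({t: "ACGT" for t in "abc"})
        tree = read_newick("(a,(b,c));")
        with pytest.raises(ValueError, match="4 taxa"):
            run_quartet_sampling(aln, tree, QSConfig(5))
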
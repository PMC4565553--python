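import numpy as np
import pytest

import cardevol as ce
from cardevol.alignment import CodonAlignment, ProteinAlignment
from cardevol.models import CodonModel, ReversibleEigen, build_rate_matrix
from cardevol.phylo import (
    LikelihoodEngine,
    neighbor_joining,
    optimize,
    root_by_duplication_loss,
    sh_test,
)
from cardevol.treeutil import LinearTree, bipartition_lengths, clone_tree

from oracles import enumeration_log_likelihood, reconcile_min_cost_bruteforce


def _weights_rates(model):
    if isinstance(model, CodonModel):
        return [(w, 1.0) for w, _, _ in model.rate_matrices()]
    rates = model.rate_multipliers()
    return [(1.0 / len(rates), r) for r in rates]


class TestPruningLikelihood:
    def test_single_taxon_closed_form(self, lg2):
        tree = ce.parse_tree("(a:0.0);")
        aln = ProteinAlignment([("a", "MKL")])
        lnl, site = ce.log_likelihood(aln, tree, lg2)
        pi = lg2.frequencies
        from cardevol.models import AA_INDEX

        expected = sum(np.log(pi[AA_INDEX[c]]) for c in "MKL")
        assert lnl == pytest.approx(expected, abs=1e-10)

    def test_matches_enumeration_protein(self, tree3, aln3, lg2):
        lnl, _ = ce.log_likelihood(aln3, tree3, lg2)
        lin = LinearTree(tree3)
        leaf_codes = {t: aln3.row(t) for t in "abc"}
        q = build_rate_matrix(lg2)
        eig = ReversibleEigen(q, lg2.frequencies)

        def trans(node, rate):
            return eig.transition(lin.lengths[node] * rate)

        oracle = enumeration_log_likelihood(
            lin, leaf_codes, trans, lg2.frequencies, _weights_rates(lg2)
        )
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_matches_enumeration_codon_branch_site(self):
        """Pruning equals state-enumeration for a 3-taxon branch-site model
        with a foreground branch (mixture over 4 site classes)."""
        tree = ce.parse_tree("((a:0.2,b:0.4):0.3,c:0.6);")
        aln = CodonAlignment([("a", "ATGAAA"), ("b", "ATGCGT"),
                              ("c", "TTGAAA")])
        model = CodonModel.branch_site_a(0.5, 0.3, 0.2, 3.0, kappa=2.0)
        fg = frozenset(["a", "b"])
        lnl, _ = ce.log_likelihood(aln, tree, model, foreground=fg)
        lin = LinearTree(tree)
        from cardevol.treeutil import find_branch_nodes

        # the root lies on the foreground branch here, so both root-adjacent
        # edges make up the (single) unrooted foreground branch
        fg_nodes = set(find_branch_nodes(lin, fg))
        leaf_codes = {t: aln.row(t) for t in "abc"}
        mats = model.rate_matrices()
        n_sites = aln.n_sites
        site_likes = np.zeros(n_sites)
        for k, (w, qb, qf) in enumerate(mats):
            eb = ReversibleEigen(qb, model.codon_freqs)
            ef = ReversibleEigen(qf, model.codon_freqs)

            def trans(node, rate, eb=eb, ef=ef):
                eig = ef if node in fg_nodes else eb
                return eig.transition(lin.lengths[node])

            # the class mixture applies per site, so enumerate per site
            for s in range(n_sites):
                sub = {t: aln.row(t)[s:s + 1] for t in "abc"}
                ll = enumeration_log_likelihood(
                    lin, sub, trans, model.codon_freqs, [(1.0, 1.0)]
                )
                site_likes[s] += w * np.exp(ll)
        oracle = np.log(site_likes).sum()
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_missing_data_treated_as_ones(self, tree3, lg2):
        aln = ProteinAlignment([("a", "MX"), ("b", "M-"), ("c", "MK")])
        lnl, site = ce.log_likelihood(aln, tree3, lg2)
        # column 2 depends on c only: marginal likelihood = pi[K]
        from cardevol.models import AA_INDEX

        assert site.values[1] == pytest.approx(
            np.log(lg2.frequencies[AA_INDEX["K"]]), abs=1e-10
        )

    def test_rerooting_invariance(self, lg2):
        tree = ce.random_tree(6, total_length=2.0, seed=21)
        sim = ce.simulate_protein_alignment(tree, lg2, 40, seed=22)
        lnl0, _ = ce.log_likelihood(sim.alignment, tree, lg2)
        work = clone_tree(tree)
        edges = [e for e in work.preorder_edge_iter()
                 if e.head_node.parent_node and not e.head_node.is_leaf()]
        half = edges[1].length / 2
        work.reroot_at_edge(edges[1], length1=half, length2=half,
                            update_bipartitions=False)
        lnl1, _ = ce.log_likelihood(sim.alignment, work, lg2)
        assert abs(lnl1 - lnl0) < 1e-8

    def test_taxon_mismatch_rejected(self, tree3, lg2):
        aln = ProteinAlignment([("a", "M"), ("b", "M"), ("z", "M")])
        with pytest.raises(ValueError, match="taxa"):
            ce.log_likelihood(aln, tree3, lg2)


class TestOptimize:
    def test_optimizing_nothing_returns_input_lnl(self, tree6, lg2):
        sim = ce.simulate_protein_alignment(tree6, lg2, 30, seed=1)
        lnl, _ = ce.log_likelihood(sim.alignment, tree6, lg2)
        res = optimize(sim.alignment, tree6, lg2, free_params=())
        assert res.lnl == pytest.approx(lnl, abs=1e-10)
        assert res.n_sweeps == 1

    def test_lnl_trajectory_monotone(self, tree6):
        model = ce.lg_model(alpha=0.8, ncat=2)
        sim = ce.simulate_protein_alignment(tree6, model, 120, seed=2)
        start = clone_tree(tree6)
        for nd in start.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length = 0.2
        res = optimize(sim.alignment, start, model,
                       free_params=("branch_lengths", "alpha"),
                       tol=1e-5, max_sweeps=20)
        diffs = np.diff(res.history)
        assert np.all(diffs >= -1e-9)

    def test_branch_length_recovery_within_15_percent(self, lg_flat):
        """Simulation recovery: branch lengths refit from 5000 sites land
        within 15% of truth (moderate-length branches)."""
        tree = ce.random_tree(6, total_length=2.0, seed=31)
        sim = ce.simulate_protein_alignment(tree, lg_flat, 5000, seed=32)
        start = clone_tree(tree)
        for nd in start.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length = 0.3
        res = optimize(sim.alignment, start, lg_flat,
                       free_params=("branch_lengths",), tol=1e-6,
                       xtol=1e-4, max_sweeps=50)
        truth = bipartition_lengths(tree)
        fitted = bipartition_lengths(res.tree)
        for k, t in truth.items():
            if t > 0.1:
                assert fitted[k] == pytest.approx(t, rel=0.15)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 10.0], [9.0, 10.0, 0.0]])
        tree = neighbor_joining(d, ["a", "b", "c"])
        lens = bipartition_lengths(tree)
        assert lens[frozenset(["b"])] == pytest.approx((5 + 10 - 9) / 2)
        assert lens[frozenset(["c"])] == pytest.approx((9 + 10 - 5) / 2)

    def test_recovers_additive_tree_exactly(self):
        source = ce.parse_tree(
            "((a:0.2,b:0.3):0.15,(c:0.25,d:0.1):0.2,e:0.4);"
        )
        lin = LinearTree(source)
        labels = sorted(lin.taxon_labels)
        # path-length (additive) distances
        idx = {lin.labels[i]: i for i in lin.leaf_indices}
        n = len(labels)
        d = np.zeros((n, n))

        def path_to_root(i):
            out = {}
            acc = 0.0
            while i != lin.root:
                acc += lin.lengths[i]
                i = lin.parent[i]
                out[i] = acc
            return out

        for x in range(n):
            px = path_to_root(idx[labels[x]])
            for y in range(x + 1, n):
                py = path_to_root(idx[labels[y]])
                common = min(
                    (px[k] + py[k] for k in px if k in py),
                )
                d[x, y] = d[y, x] = common
        tree = neighbor_joining(d, labels)
        got = bipartition_lengths(tree)
        want = bipartition_lengths(source)
        assert set(got) == set(want)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-10)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.random((6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(6)]
        t1 = neighbor_joining(d, labels)
        perm = rng.permutation(6)
        t2 = neighbor_joining(d[np.ix_(perm, perm)], [labels[i] for i in perm])
        b1, b2 = bipartition_lengths(t1), bipartition_lengths(t2)
        assert set(b1) == set(b2)
        for k in b1:
            assert b1[k] == pytest.approx(b2[k], abs=1e-10)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, list("abc"))


class TestSHTest:
    def test_identical_candidates_get_p_one(self, tree6, lg_flat):
        sim = ce.simulate_protein_alignment(tree6, lg_flat, 60, seed=41)
        res = sh_test(sim.alignment, [tree6, clone_tree(tree6)], lg_flat,
                      n_rell=200, seed=0,
                      optimize_kwargs={"tol": 1e-4, "max_sweeps": 5})
        assert np.allclose(res.p_values, 1.0)
        assert np.allclose(res.delta, 0.0, atol=1e-6)

    def test_best_tree_p_is_one_and_p_in_range(self, lg_flat):
        true = ce.parse_tree("((a:0.2,b:0.2):0.3,(c:0.2,d:0.2):0.3);")
        wrong = ce.parse_tree("((a:0.2,c:0.2):0.3,(b:0.2,d:0.2):0.3);")
        sim = ce.simulate_protein_alignment(true, lg_flat, 300, seed=42)
        res = sh_test(sim.alignment, [true, wrong], lg_flat, n_rell=500,
                      seed=1, optimize_kwargs={"tol": 1e-4, "max_sweeps": 10})
        assert res.p_values[res.best_index] == 1.0
        assert np.all((res.p_values >= 0) & (res.p_values <= 1))

    def test_seed_reproducibility(self, lg_flat):
        true = ce.parse_tree("((a:0.2,b:0.2):0.3,(c:0.2,d:0.2):0.3);")
        wrong = ce.parse_tree("((a:0.2,c:0.2):0.3,(b:0.2,d:0.2):0.3);")
        sim = ce.simulate_protein_alignment(true, lg_flat, 150, seed=4)
        kw = {"tol": 1e-4, "max_sweeps": 5}
        r1 = sh_test(sim.alignment, [true, wrong], lg_flat, n_rell=300,
                     seed=7, optimize_kwargs=kw)
        r2 = sh_test(sim.alignment, [true, wrong], lg_flat, n_rell=300,
                     seed=7, optimize_kwargs=kw)
        assert np.array_equal(r1.p_values, r2.p_values)

    def test_power_against_wrong_topology(self, lg_flat):
        """Data simulated on tree A with distinct clans: the perturbed
        topology is rejected (p < 0.05) in >= 90% of seeds."""
        true = ce.parse_tree(
            "(((a:0.1,b:0.1):0.4,(c:0.1,d:0.1):0.4):0.2,(e:0.1,f:0.1):0.4);"
        )
        wrong = ce.parse_tree(
            "(((a:0.1,c:0.1):0.4,(b:0.1,d:0.1):0.4):0.2,(e:0.1,f:0.1):0.4);"
        )
        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            sim = ce.simulate_protein_alignment(true, lg_flat, 2000,
                                                seed=500 + seed)
            res = sh_test(sim.alignment, [true, wrong], lg_flat, n_rell=500,
                          seed=seed,
                          optimize_kwargs={"tol": 1e-3, "xtol": 1e-2,
                                           "max_sweeps": 5})
            rejections += res.p_values[1] < 0.05
        assert rejections >= 18


class TestDuplicationLossRooting:
    def test_congruent_tree_roots_at_zero_cost(self):
        species = ce.parse_tree("(((A,B),C),D);")
        gene = ce.parse_tree("((a_A:1,b_B:1):1,(c_C:1,d_D:1):1);")
        res = root_by_duplication_loss(gene, species,
                                       label_map=lambda x: x.split("_")[1])
        d, l = res.best_cost()
        assert (d, l) == (0, 0)

    def test_costs_match_bruteforce_enumeration(self):
        """Every candidate root's dup+loss cost equals the exhaustive
        minimum over all valid gene-to-species mappings."""
        species = ce.parse_tree("(((A,B),(C,D)),(E,F));")
        gene = ce.parse_tree(
            "((gA_A:1,gC_C:1):1,((gB_B:1,gE_E:1):1,(gD_D:1,gF_F:1):1):1);"
        )
        res = root_by_duplication_loss(gene, species,
                                       label_map=lambda x: x.split("_")[1])
        # rebuild each rooting and brute-force it
        from cardevol.phylo import reconcile_costs

        sp_lin = LinearTree(species)
        depth = {}
        ancestors = {i: set() for i in range(sp_lin.n_nodes)}
        for i in range(sp_lin.n_nodes - 1, -1, -1):
            p = sp_lin.parent[i]
            depth[i] = 0 if p < 0 else depth[p] + 1
            if p >= 0:
                ancestors[i] = ancestors[p] | {p}
        leaf_idx = {sp_lin.labels[i]: i for i in sp_lin.leaf_indices}

        base = clone_tree(gene)
        base.deroot()
        edges = [e for e in base.preorder_edge_iter()
                 if e.head_node.parent_node]
        for k in range(len(edges)):
            work = clone_tree(base)
            es = [e for e in work.preorder_edge_iter()
                  if e.head_node.parent_node]
            work.reroot_at_edge(es[k], update_bipartitions=False)
            d, l = reconcile_costs(work, species,
                                   label_map=lambda x: x.split("_")[1])
            g_lin = LinearTree(work)
            best = reconcile_min_cost_bruteforce(
                g_lin, sp_lin, depth, ancestors,
                {lab: leaf_idx[lab.split("_")[1]] for lab in g_lin.taxon_labels},
            )
            assert d + l == best

    def test_tandem_duplication_costs_one_duplication(self):
        """Two copies of every species subtree: optimal rooting implies
        exactly one duplication (at the root) and no losses."""
        species = ce.parse_tree("((A,B),C);")
        gene = ce.parse_tree(
            "(((x_A:1,x_B:1):1,x_C:1):1,((y_A:1,y_B:1):1,y_C:1):1);"
        )
        res = root_by_duplication_loss(gene, species,
                                       label_map=lambda x: x.split("_")[1])
        d, l = res.best_cost()
        assert (d, l) == (1, 0)

    def test_unmappable_leaf_rejected(self):
        species = ce.parse_tree("((A,B),C);")
        gene = ce.parse_tree("((x:1,y:1):1,z:1);")
        with pytest.raises(ValueError, match="unknown species"):
            root_by_duplication_loss(gene, species)
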
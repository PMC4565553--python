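import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardevol as ce
from cardevol.alignment import CodonAlignment
from cardevol.io import SequenceRecord
from cardevol.models import CODONS, CodonModel
from cardevol.phylo import LikelihoodEngine, optimize
from cardevol.selection import (
    bonferroni,
    branch_sites_lrt,
    gene_conversion_scan,
    _max_fragment,
    _max_scores_batch,
)

from oracles import best_fragment_bruteforce


class TestBranchSitesLRT:
    @pytest.fixture(scope="class")
    def fixture(self):
        tree = ce.parse_tree("((a:0.3,b:0.4):0.25,(c:0.35,d:0.3):0.25);")
        model = CodonModel.sites(0.6, 0.15, kappa=2.0)
        sim = ce.simulate_codon_alignment(tree, model, 30, regime="sites",
                                          seed=77)
        return sim.alignment, tree

    def test_nesting_alt_at_least_null(self, fixture):
        aln, tree = fixture
        res = branch_sites_lrt(aln, tree, frozenset(["a", "b"]), m_tests=2)
        assert res.lnl_alt >= res.lnl_null - 1e-6
        assert res.statistic >= 0.0
        assert res.p_bonferroni == pytest.approx(min(1.0, 2 * res.p_raw))

    def test_model_a_fit_matches_grid_oracle(self, fixture):
        """Null and alternative model-A fits on a 4-taxon 30-codon fixture
        reach the brute-force grid optimum over (p0, p1, omega0, omega2)
        within 0.05 lnL units (branch lengths and kappa fixed)."""
        aln, tree = fixture
        fg = frozenset(["a", "b"])
        kappa = 2.0

        def scan(engine, model, grids):
            best, best_pt = -np.inf, None
            for w0 in grids["omega0"]:
                for w2 in grids["omega2"]:
                    for p0 in grids["p0"]:
                        for p1 in grids["p1"]:
                            if p0 <= 0 or p1 <= 0 or p0 + p1 >= 1.0 - 1e-9:
                                continue
                            model.params.update(
                                p0=p0, p1=p1, omega0=w0, omega2=w2
                            )
                            engine.invalidate_model()
                            lnl = engine.log_likelihood()
                            if lnl > best:
                                best, best_pt = lnl, (w0, w2, p0, p1)
            return best, best_pt

        def grid_best(null):
            model = CodonModel.branch_site_a(0.4, 0.4, 0.2, 1.0, kappa=kappa)
            engine = LikelihoodEngine(aln, tree, model, foreground=fg)
            coarse = {
                "omega0": np.arange(0.05, 1.0, 0.05),
                "omega2": [1.0] if null else np.concatenate(
                    [[1.0], np.arange(1.2, 3.01, 0.2),
                     np.arange(3.5, 8.1, 0.5)]
                ),
                "p0": np.concatenate([np.arange(0.1, 1.0, 0.1),
                                      [0.001, 0.99, 0.999]]),
                "p1": np.concatenate([np.arange(0.1, 1.0, 0.1),
                                      [0.001, 0.99, 0.999]]),
            }
            _, (w0, w2, p0, p1) = scan(engine, model, coarse)
            edge = [1e-5, 1e-4, 1e-3, 0.005, 0.995, 0.999, 0.9999]
            fine = {
                "omega0": np.clip(w0 + np.arange(-0.05, 0.051, 0.01),
                                  1e-3, 0.9999),
                "omega2": [1.0] if null else np.clip(
                    w2 + np.arange(-0.1, 0.101, 0.04), 1.0, None
                ),
                # mixture proportions can sit on the simplex boundary, so
                # the refined grid includes near-boundary candidates
                "p0": np.concatenate([p0 + np.arange(-0.05, 0.051, 0.01),
                                      edge]),
                "p1": np.concatenate([p1 + np.arange(-0.05, 0.051, 0.01),
                                      edge]),
            }
            best, _ = scan(engine, model, fine)
            return best

        res = branch_sites_lrt(aln, tree, fg, kappa=kappa,
                               fit_branch_lengths=False, tol=1e-6,
                               xtol=1e-4, max_sweeps=60)
        assert res.lnl_null == pytest.approx(grid_best(null=True), abs=0.05)
        assert res.lnl_alt == pytest.approx(grid_best(null=False), abs=0.05)

    def test_conservative_under_null_simulation(self):
        """Raw p-values on data simulated without positive selection exceed
        0.05 in >= 90% of seeds (the boundary null is conservative)."""
        tree = ce.parse_tree(
            "(((a:0.2,b:0.3):0.2,c:0.4):0.1,(d:0.3,e:0.2):0.2);"
        )
        model = CodonModel.sites(0.5, 0.2, kappa=2.0)
        fg = frozenset(["a", "b"])
        hits = 0
        for seed in range(20):
            sim = ce.simulate_codon_alignment(tree, model, 50,
                                              regime="sites", seed=900 + seed)
            res = branch_sites_lrt(sim.alignment, tree, fg)
            hits += res.p_raw > 0.05
        assert hits >= 18

    def test_statistic_invariant_to_taxon_order(self, fixture):
        aln, tree = fixture
        rev = CodonAlignment(list(reversed(aln.records)))
        fg = frozenset(["a", "b"])
        r1 = branch_sites_lrt(aln, tree, fg, fit_branch_lengths=False)
        r2 = branch_sites_lrt(rev, tree, fg, fit_branch_lengths=False)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-6)

    def test_likelihood_invariant_to_rerooting_off_foreground(self, fixture):
        """The branch-site likelihood with a fixed foreground bipartition is
        unchanged when the tree is rerooted along a background path."""
        aln, tree = fixture
        fg = frozenset(["a", "b"])
        model = CodonModel.branch_site_a(0.5, 0.3, 0.2, 2.0, kappa=2.0)
        lnl0, _ = ce.log_likelihood(aln, tree, model, foreground=fg)
        from cardevol.treeutil import clone_tree

        work = clone_tree(tree)
        edges = [e for e in work.preorder_edge_iter()
                 if e.head_node.parent_node and e.head_node.is_leaf()
                 and e.head_node.taxon.label == "c"]
        half = edges[0].length / 2
        work.reroot_at_edge(edges[0], length1=half, length2=half,
                            update_bipartitions=False)
        lnl1, _ = ce.log_likelihood(aln, work, model, foreground=fg)
        assert lnl1 == pytest.approx(lnl0, abs=1e-8)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment([("a", "ATGTAA"), ("b", "ATGAAA"),
                            ("c", "ATGAAA")])


class TestBonferroni:
    def test_worked_examples(self):
        assert np.allclose(bonferroni([0.01, 0.5]), [0.02, 1.0])
        assert np.allclose(bonferroni([0.2]), [0.2])
        assert bonferroni([0.4], m=3)[0] == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_outputs_valid_and_monotone(self, ps):
        adj = bonferroni(ps)
        assert np.all((adj >= 0) & (adj <= 1))
        assert np.all(adj >= np.asarray(ps) - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


def _mosaic_records(seed=0, n_cols=80, tract=(20, 40)):
    """Four DNA sequences, random noisy columns, with sequences A and B
    sharing an identical tract (and disagreeing elsewhere)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    mat = bases[rng.integers(0, 4, size=(4, n_cols))]
    # force polymorphism and A-B disagreement outside the tract
    for c in range(n_cols):
        if tract[0] <= c < tract[1]:
            mat[1, c] = mat[0, c]          # A == B inside the tract
            if mat[2, c] == mat[0, c]:
                mat[2, c] = bases[(np.where(bases == mat[0, c])[0][0] + 1) % 4]
        else:
            choices = [b for b in "ACGT" if b != mat[0, c]]
            mat[1, c] = choices[rng.integers(0, 3)]
    return [SequenceRecord(n, "".join(row))
            for n, row in zip("ABCD", mat)]


class TestGeneConversionScan:
    def test_identical_sequences_give_empty_result(self):
        recs = [SequenceRecord(n, "ACGTACGT") for n in "abc"]
        with pytest.warns(UserWarning, match="polymorphic"):
            assert gene_conversion_scan(recs, n_perm=10, seed=0) == []

    def test_constructed_tract_detected(self):
        """A 20-column shared tract between A and B is the top fragment with
        sim_p <= 0.01 at 1000 permutations, and its score matches the
        brute-force all-fragments scan."""
        recs = _mosaic_records(seed=3)
        frags = gene_conversion_scan(recs, n_perm=1000, seed=1)
        top = frags[0]
        assert set(top.pair) == {"A", "B"}
        assert top.sim_p <= 0.01
        assert top.begin <= 21 and top.end >= 40  # covers the tract
        # oracle: brute-force max fragment on the same agreement vector
        mat = np.array([list(r.seq) for r in recs])
        poly = np.where(np.any(mat != mat[0], axis=0))[0]
        values = np.where(mat[0, poly] == mat[1, poly], 1.0, -1.0)
        oracle_score, _, _ = best_fragment_bruteforce(values)
        assert top.score == pytest.approx(oracle_score)

    def test_kadane_equals_bruteforce_on_random_vectors(self, rng):
        for _ in range(30):
            vals = rng.choice([1.0, -1.0], size=rng.integers(2, 40))
            s1, a1, b1 = _max_fragment(vals)
            s2, a2, b2 = best_fragment_bruteforce(vals)
            assert s1 == pytest.approx(s2)
            batch = _max_scores_batch(vals[np.newaxis, :])
            assert batch[0] == pytest.approx(s2)

    def test_null_pvalues_approximately_uniform(self):
        """On exchangeable (i.i.d.-column) data the permutation p-value for
        a fixed pair is approximately Uniform(0,1) across datasets."""
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        ps = []
        for _ in range(120):
            mat = bases[rng.integers(0, 4, size=(4, 60))]
            recs = [SequenceRecord(n, "".join(row))
                    for n, row in zip("abcd", mat)]
            frags = gene_conversion_scan(recs, n_perm=199,
                                         seed=int(rng.integers(2 ** 31)))
            pair_p = {f.pair: f.sim_p for f in frags}
            if ("a", "b") in pair_p:
                ps.append(pair_p[("a", "b")])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_seed_reproducibility_and_p_range(self):
        recs = _mosaic_records(seed=5)
        f1 = gene_conversion_scan(recs, n_perm=200, seed=9)
        f2 = gene_conversion_scan(recs, n_perm=200, seed=9)
        assert [f.sim_p for f in f1] == [f.sim_p for f in f2]
        for f in f1:
            assert 1 / 201 <= f.sim_p <= 1.0

    def test_permutation_p_monotone_in_score(self):
        """Within one null distribution, the exceedance p-value is monotone
        non-increasing in the observed score."""
        rng = np.random.default_rng(2)
        vals = rng.choice([1.0, -1.0], size=50)
        perms = rng.permuted(np.tile(vals, (500, 1)), axis=1)
        null = _max_scores_batch(perms)
        ps = [(1 + np.count_nonzero(null >= s)) / 501 for s in (3, 5, 8, 12)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            gene_conversion_scan([SequenceRecord("a", "ACGT"),
                                  SequenceRecord("b", "ACGA")])
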
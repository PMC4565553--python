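"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by exhaustive enumeration, closed form
or naive dynamic programming, sharing no code path with the package
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumeration_log_likelihood(lin, leaf_codes, transition_for, freqs,
                               weights_rates):
    """Total log-likelihood by summing over all internal-node state
    assignments and mixture components.

    ``lin`` is a LinearTree; ``leaf_codes[label]`` gives per-site codes
    (-1 = missing); ``transition_for(node, rate)`` returns the branch P
    matrix; ``weights_rates`` is a list of (weight, rate).
    """
    n_states = len(freqs)
    internals = lin.internal_indices
    n_sites = len(next(iter(leaf_codes.values())))
    total = 0.0
    for site in range(n_sites):
        like = 0.0
        for w, rate in weights_rates:
            ps = {n: transition_for(n, rate) for n in lin.branch_nodes()}
            for assign in itertools.product(range(n_states),
                                            repeat=len(internals)):
                states = dict(zip(internals, assign))
                term = freqs[states[lin.root]]
                for i in lin.branch_nodes():
                    parent_state = states[lin.parent[i]]
                    if lin.children[i]:
                        term *= ps[i][parent_state, states[i]]
                    else:
                        code = leaf_codes[lin.labels[i]][site]
                        if code < 0:
                            term *= 1.0
                        else:
                            term *= ps[i][parent_state, code]
                like += w * term
        total += np.log(like)
    return total


def enumeration_marginal_posterior(lin, leaf_codes, transition_for, freqs,
                                   weights_rates, node, site):
    """Marginal posterior over states at one internal node / site by
    brute-force Bayes over all internal assignments."""
    n_states = len(freqs)
    internals = lin.internal_indices
    post = np.zeros(n_states)
    for w, rate in weights_rates:
        ps = {n: transition_for(n, rate) for n in lin.branch_nodes()}
        for assign in itertools.product(range(n_states), repeat=len(internals)):
            states = dict(zip(internals, assign))
            term = w * freqs[states[lin.root]]
            for i in lin.branch_nodes():
                parent_state = states[lin.parent[i]]
                if lin.children[i]:
                    term *= ps[i][parent_state, states[i]]
                else:
                    code = leaf_codes[lin.labels[i]][site]
                    term *= 1.0 if code < 0 else ps[i][parent_state, code]
            post[states[node]] += term
    return post / post.sum()


def fitch_min_changes(lin, leaf_states_site):
    """Minimum number of 0/1 state changes over all internal labelings, by
    exhaustive search; returns (min_changes, set of optimal labelings)."""
    internals = lin.internal_indices
    best = None
    optimal = set()
    for assign in itertools.product((0, 1), repeat=len(internals)):
        states = dict(zip(internals, assign))
        for i in lin.leaf_indices:
            states[i] = int(leaf_states_site[lin.labels[i]])
        changes = sum(
            states[i] != states[lin.parent[i]] for i in lin.branch_nodes()
        )
        if best is None or changes < best:
            best = changes
            optimal = {assign}
        elif changes == best:
            optimal.add(assign)
    return best, optimal


def smith_waterman(a: str, b: str, matrix, gap_open: float = 12.0,
                   gap_extend: float = 1.0) -> float:
    """Naive affine-gap local-alignment DP (first gap position costs
    ``gap_open``, each further position ``gap_extend``)."""
    n, m = len(a), len(b)
    neg = -1e18
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)   # gap in a (consume b)
    f = np.full((n + 1, m + 1), neg)   # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i, j] = max(h[i, j - 1] - gap_open, e[i, j - 1] - gap_extend)
            f[i, j] = max(h[i - 1, j] - gap_open, f[i - 1, j] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            h[i, j] = max(0.0, h[i - 1, j - 1] + s, e[i, j], f[i, j])
            best = max(best, h[i, j])
    return best


def best_fragment_bruteforce(values):
    """Maximal-scoring contiguous fragment by trying every (start, end)."""
    values = np.asarray(values, float)
    best, bs, be = 0.0, -1, -1
    n = len(values)
    for s in range(n):
        acc = 0.0
        for e in range(s, n):
            acc += values[e]
            if acc > best:
                best, bs, be = acc, s, e
    return best, bs, be


def reconcile_min_cost_bruteforce(gene_lin, species_lin, species_depth,
                                  species_ancestors, leaf_to_species):
    """Minimum duplication + loss cost over ALL valid mappings of gene-tree
    internals into the species tree (each node mapped at or above the LCA of
    its children's mappings); the loss count per mapping uses the standard
    path-length formula.  Exponential search for small trees."""
    internals = gene_lin.internal_indices
    leaf_map = {i: leaf_to_species[gene_lin.labels[i]]
                for i in gene_lin.leaf_indices}
    candidates = list(range(species_lin.n_nodes))
    best = None
    for assign in itertools.product(candidates, repeat=len(internals)):
        mapping = dict(leaf_map)
        mapping.update(dict(zip(internals, assign)))
        ok = True
        dups = losses = 0
        for g in internals:
            kids = gene_lin.children[g]
            m = mapping[g]
            anc_m = species_ancestors[m] | {m}
            for c in kids:
                if mapping[c] != m and m not in species_ancestors[mapping[c]]:
                    ok = False
                    break
            if not ok:
                break
            is_dup = any(mapping[c] == m for c in kids)
            dups += is_dup
            for c in kids:
                gap = species_depth[mapping[c]] - species_depth[m]
                losses += gap if is_dup else gap - 1
        if ok:
            cost = dups + losses
            if best is None or cost < best:
                best = cost
    return best


def nei_gojobori(codons_a, codons_b, codon_table):
    """NG86 pairwise dN/dS estimate (proportions, no correction).

    ``codons_a/b`` are codon-string lists; ``codon_table`` maps codon to
    amino acid.  Pathways through multi-difference codons are averaged.
    Returns (pN, pS, N_sites, S_sites).
    """
    bases = "TCAG"

    def site_counts(codon):
        s = 0.0
        for pos in range(3):
            for b in bases:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if mut not in codon_table:
                    continue  # stop codons excluded from mutational paths
                if codon_table[mut] == codon_table[codon]:
                    s += 1.0 / 3.0
        return s, 3.0 - s

    def diff_counts(c1, c2):
        diffs = [p for p in range(3) if c1[p] != c2[p]]
        if not diffs:
            return 0.0, 0.0
        paths = []
        for order in itertools.permutations(diffs):
            cur = c1
            sd = nd = 0
            valid = True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if nxt not in codon_table:
                    valid = False
                    break
                if codon_table[nxt] == codon_table[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if valid:
                paths.append((sd, nd))
        if not paths:
            return 0.0, float(len(diffs))
        sd = np.mean([p[0] for p in paths])
        nd = np.mean([p[1] for p in paths])
        return sd, nd

    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        s1, n1 = site_counts(ca)
        s2, n2 = site_counts(cb)
        S += 0.5 * (s1 + s2)
        N += 0.5 * (n1 + n2)
        sd, nd = diff_counts(ca, cb)
        Sd += sd
        Nd += nd
    return Nd / N, Sd / S, N, S
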
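"""Likelihood computation and inference on fixed topologies.

Felsenstein pruning over discrete rate/omega mixtures, coordinate-ascent
parameter and branch-length optimization, neighbor joining, the
Shimodaira-Hasegawa topology test with RELL bootstrapping, and
duplication/loss (reconciliation) rooting of gene trees.

Tree topologies are inputs throughout; no tree search is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import CodonAlignment, ProteinAlignment
from .models import (
    CodonModel,
    ProteinModel,
    ReversibleEigen,
    build_rate_matrix,
    stationary_frequencies,
)
from .treeutil import LinearTree, clone_tree, find_branch_nodes, leafset

__all__ = [
    "SiteLikelihoods",
    "LikelihoodEngine",
    "log_likelihood",
    "FitResult",
    "optimize",
    "neighbor_joining",
    "SHResult",
    "sh_test",
    "RootingResult",
    "root_by_duplication_loss",
]


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods for one (alignment, tree, model) triple."""

    values: np.ndarray

    @property
    def total(self) -> float:
        return float(self.values.sum())


class _Component:
    """One mixture component: weight, background/foreground eigendecomposed
    generators and a relative rate multiplier."""

    __slots__ = ("weight", "eig_bg", "eig_fg", "rate")

    def __init__(self, weight, eig_bg, eig_fg, rate=1.0):
        self.weight = weight
        self.eig_bg = eig_bg
        self.eig_fg = eig_fg
        self.rate = rate


class LikelihoodEngine:
    """Pruning likelihood for a fixed alignment/topology pair.

    Gaps, ``X`` and ambiguous codons are treated as missing data (partial
    vector of ones).  The ``foreground`` argument, a leaf-set bipartition,
    marks the single branch on which foreground generators apply (branch-site
    models); all other branches use background generators.
    """

    def __init__(self, alignment, tree, model, foreground=None):
        self.alignment = alignment
        self.tree = tree
        self.model = model
        self.lin = LinearTree(tree)
        if self.lin.taxon_labels != alignment.taxon_set:
            missing = self.lin.taxon_labels ^ alignment.taxon_set
            raise ValueError(
                f"taxa differ between tree and alignment: {sorted(missing)}"
            )
        self.n_states = alignment.n_states
        self.n_sites = alignment.n_sites
        self.foreground_nodes = (
            frozenset() if foreground is None
            else frozenset(find_branch_nodes(self.lin, foreground))
        )
        self._leaf_partials = {}
        eye = np.eye(self.n_states)
        ones = np.ones(self.n_states)
        for i in self.lin.leaf_indices:
            codes = alignment.row(self.lin.labels[i])
            part = np.where(codes[np.newaxis, :] >= 0,
                            eye[:, np.clip(codes, 0, None)].reshape(
                                self.n_states, -1),
                            ones[:, np.newaxis])
            self._leaf_partials[i] = np.ascontiguousarray(part)
        self._components: list[_Component] | None = None
        self._eig_cache: dict[bytes, ReversibleEigen] = {}
        self._p_cache: dict[tuple, np.ndarray] = {}

    # -- model mixture ------------------------------------------------------
    def invalidate_model(self) -> None:
        # P matrices are keyed by eigensystem identity, so entries for
        # unchanged mixture components stay valid across parameter moves
        self._components = None

    def invalidate_branch(self, node_index: int) -> None:
        self._p_cache = {k: v for k, v in self._p_cache.items()
                         if k[0] != node_index}

    def _eig(self, Q: np.ndarray, pi: np.ndarray) -> ReversibleEigen:
        key = Q.tobytes()
        eig = self._eig_cache.get(key)
        if eig is None:
            if len(self._eig_cache) > 256:
                # p-cache entries are keyed by eigensystem identity; drop
                # them too so recycled ids cannot alias stale matrices
                self._eig_cache.clear()
                self._p_cache.clear()
            eig = ReversibleEigen(Q, pi)
            self._eig_cache[key] = eig
        return eig

    def components(self) -> list[_Component]:
        if self._components is not None:
            return self._components
        model = self.model
        if isinstance(model, ProteinModel):
            Q = build_rate_matrix(model)
            eig = self._eig(Q, model.frequencies)
            rates = model.rate_multipliers()
            w = 1.0 / len(rates)
            comps = [_Component(w, eig, eig, r) for r in rates]
        elif isinstance(model, CodonModel):
            # eigendecompose unnormalized per-omega generators (cacheable
            # across proportion moves) and fold the mixture scaling into
            # the component rate
            from .models import codon_rate_matrix

            classes = model.site_classes()
            pi = model.codon_freqs
            q_of = {}
            for sc in classes:
                for w in (sc.omega_background, sc.omega_foreground):
                    if w not in q_of:
                        q_of[w] = codon_rate_matrix(model.kappa, w, pi,
                                                    normalize=False)
            scale = sum(
                sc.proportion * -(pi * np.diag(q_of[sc.omega_background])).sum()
                for sc in classes
            )
            comps = [
                _Component(
                    sc.proportion,
                    self._eig(q_of[sc.omega_background], pi),
                    self._eig(q_of[sc.omega_foreground], pi),
                    1.0 / scale,
                )
                for sc in classes
            ]
        else:
            raise TypeError(f"unsupported model {type(model).__name__}")
        self._components = comps
        return comps

    def _transition(self, node_index: int, comp_index: int) -> np.ndarray:
        comp = self.components()[comp_index]
        t = self.lin.lengths[node_index] * comp.rate
        eig = (comp.eig_fg if node_index in self.foreground_nodes
               else comp.eig_bg)
        key = (node_index, t, id(eig))
        p = self._p_cache.get(key)
        if p is None:
            if len(self._p_cache) > 4096:
                self._p_cache.clear()
            p = eig.transition(t)
            self._p_cache[key] = p
        return p

    # -- pruning ------------------------------------------------------------
    def _prune_component(self, comp_index: int, keep_partials: bool = False):
        """Post-order pruning for one component.  Returns per-site log
        likelihood; optionally also the scaled partials and per-node
        log-scalers (for marginal reconstruction)."""
        lin = self.lin
        pi = stationary_frequencies(self.model)
        partials: list[np.ndarray | None] = [None] * lin.n_nodes
        logscale = [None] * lin.n_nodes
        zero_scale = np.zeros(self.n_sites)
        for i in range(lin.n_nodes):
            kids = lin.children[i]
            if not kids:
                partials[i] = self._leaf_partials[i]
                logscale[i] = zero_scale
                continue
            prod = None
            ls = np.zeros(self.n_sites)
            for c in kids:
                contrib = self._transition(c, comp_index) @ partials[c]
                prod = contrib if prod is None else prod * contrib
                ls += logscale[c]
            m = prod.max(axis=0)
            safe = np.where(m > 0, m, 1.0)
            prod = prod / safe
            with np.errstate(divide="ignore"):
                ls = ls + np.log(safe) + np.where(m > 0, 0.0, -np.inf)
            partials[i] = prod
            logscale[i] = ls
        root_like = pi @ partials[lin.root]
        with np.errstate(divide="ignore"):
            site_lnl = np.log(root_like) + logscale[lin.root]
        if keep_partials:
            return site_lnl, partials, logscale
        return site_lnl

    def site_log_likelihoods(self) -> np.ndarray:
        comps = self.components()
        stacked = np.stack(
            [self._prune_component(k) for k in range(len(comps))]
        )
        logw = np.log(np.array([c.weight for c in comps]))
        return logsumexp(stacked + logw[:, np.newaxis], axis=0)

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods().sum())

    # -- marginal ancestral posteriors --------------------------------------
    def marginal_posteriors(self) -> dict[int, np.ndarray]:
        """Empirical-Bayes marginal posteriors P(state | data) per internal
        node (keyed by linear-tree node index), summed over mixture
        components: (n_sites, n_states) arrays summing to 1 per site."""
        lin = self.lin
        pi = stationary_frequencies(self.model)
        comps = self.components()
        numerators = {i: [] for i in lin.internal_indices}
        scales = {i: [] for i in lin.internal_indices}
        site_lnl_comp = []
        for k, comp in enumerate(comps):
            site_lnl, down, dscale = self._prune_component(k, keep_partials=True)
            site_lnl_comp.append(site_lnl)
            up: list[np.ndarray | None] = [None] * lin.n_nodes
            uscale: list[np.ndarray | None] = [None] * lin.n_nodes
            up[lin.root] = np.ones((self.n_states, self.n_sites))
            uscale[lin.root] = np.zeros(self.n_sites)
            # preorder = reversed postorder
            for i in range(lin.n_nodes - 1, -1, -1):
                kids = lin.children[i]
                if not kids:
                    continue
                contribs = {c: self._transition(c, k) @ down[c] for c in kids}
                for c in kids:
                    if not lin.children[c]:
                        continue
                    g = up[i].copy()
                    gs = uscale[i].copy()
                    for s in kids:
                        if s != c:
                            g = g * contribs[s]
                            gs = gs + dscale[s]
                    u = self._transition(c, k) @ g
                    m = u.max(axis=0)
                    safe = np.where(m > 0, m, 1.0)
                    up[c] = u / safe
                    with np.errstate(divide="ignore"):
                        uscale[c] = gs + np.log(safe) + np.where(m > 0, 0.0, -np.inf)
            for i in lin.internal_indices:
                num = pi[:, np.newaxis] * down[i] * up[i]
                numerators[i].append(num)
                scales[i].append(dscale[i] + uscale[i])
        logw = np.log(np.array([c.weight for c in comps]))
        site_lnl_total = logsumexp(
            np.stack(site_lnl_comp) + logw[:, np.newaxis], axis=0
        )
        out = {}
        for i in lin.internal_indices:
            # combine components on a common per-site scale
            sc = np.stack(scales[i]) + logw[:, np.newaxis]
            ref = sc.max(axis=0)
            weights = np.exp(sc - ref)
            total = np.zeros((self.n_states, self.n_sites))
            for k in range(len(comps)):
                total += numerators[i][k] * weights[k]
            denom = np.exp(site_lnl_total - ref)
            post = (total / denom).T
            post = post / post.sum(axis=1, keepdims=True)
            out[i] = post
        return out


def log_likelihood(alignment, tree, model, foreground=None):
    """Total log-likelihood plus per-site log-likelihoods by Felsenstein
    pruning over rate categories.  Invariant to root placement for these
    reversible models."""
    engine = LikelihoodEngine(alignment, tree, model, foreground=foreground)
    site = engine.site_log_likelihoods()
    return float(site.sum()), SiteLikelihoods(site)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

#: search bounds per free scalar parameter
PARAM_BOUNDS = {
    "alpha": (0.05, 20.0),
    "kappa": (0.01, 30.0),
    "omega": (1e-4, 20.0),
    "omega0": (1e-4, 1.0),
    "omega2": (1.0, 50.0),
}
BRANCH_BOUNDS = (1e-8, 50.0)
PROPORTION_BOUNDS = (1e-6, 1.0 - 1e-6)


@dataclass
class FitResult:
    model: object
    tree: dendropy.Tree
    lnl: float
    site_lnl: SiteLikelihoods
    n_sweeps: int
    converged: bool
    history: list = field(default_factory=list)


def _get_param(model, name: str) -> float:
    if isinstance(model, ProteinModel):
        if name == "alpha":
            return model.alpha
    elif isinstance(model, CodonModel):
        if name == "kappa":
            return model.kappa
        if name == "ptot" and {"p0", "p1"} <= model.params.keys():
            return model.params["p0"] + model.params["p1"]
        if name == "frac" and {"p0", "p1"} <= model.params.keys():
            s = model.params["p0"] + model.params["p1"]
            return model.params["p0"] / s
        if name in model.params:
            return model.params[name]
    raise KeyError(f"model has no free parameter {name!r}")


def _set_param(model, name: str, value: float) -> None:
    if isinstance(model, ProteinModel):
        if name == "alpha":
            model.alpha = float(value)
            return
    elif isinstance(model, CodonModel):
        if name == "kappa":
            model.kappa = float(value)
            return
        # (ptot, frac) reparameterize (p0, p1) as their sum and p0's share;
        # the coordinates are far less correlated in the likelihood surface
        if name == "ptot" and {"p0", "p1"} <= model.params.keys():
            f = model.params["p0"] / (model.params["p0"] + model.params["p1"])
            model.params["p0"] = float(value) * f
            model.params["p1"] = float(value) * (1.0 - f)
            return
        if name == "frac" and {"p0", "p1"} <= model.params.keys():
            s = model.params["p0"] + model.params["p1"]
            model.params["p0"] = s * float(value)
            model.params["p1"] = s * (1.0 - float(value))
            return
        if name in model.params:
            model.params[name] = float(value)
            return
    raise KeyError(f"model has no free parameter {name!r}")


def _param_bounds(model, name: str) -> tuple[float, float]:
    if name in ("ptot", "frac"):
        return PROPORTION_BOUNDS
    if name in ("p0", "p1"):
        lo, hi = PROPORTION_BOUNDS
        if isinstance(model, CodonModel) and model.kind == "branch_site":
            other = "p1" if name == "p0" else "p0"
            hi = min(hi, 1.0 - model.params[other] - 1e-6)
        return lo, hi
    return PARAM_BOUNDS[name]


def optimize(alignment, tree, model, free_params=("branch_lengths",),
             foreground=None, tol: float = 1e-6, max_sweeps: int = 200,
             xtol: float = 1e-3, copy: bool = True) -> FitResult:
    """Coordinate-ascent maximum likelihood on a fixed topology.

    ``free_params`` may contain ``"branch_lengths"`` plus scalar parameter
    names (``alpha``, ``kappa``, ``omega``, ``omega0``, ``omega2``, ``p0``,
    ``p1``).  Each scalar gets a bounded Brent line search (positive
    parameters are searched on a log scale); a proposed move is kept only if
    it improves the likelihood, so the lnL trajectory is monotone
    non-decreasing.  Convergence: sweep improvement below ``tol`` or
    ``max_sweeps`` sweeps.
    """
    if copy:
        tree = clone_tree(tree)
    if isinstance(model, CodonModel):
        model = model.copy()
    elif isinstance(model, ProteinModel):
        model = ProteinModel(model.exchangeabilities.copy(),
                             model.frequencies.copy(),
                             alpha=model.alpha, ncat=model.ncat,
                             name=model.name)
    engine = LikelihoodEngine(alignment, tree, model, foreground=foreground)
    scalar_params = [p for p in free_params if p != "branch_lengths"]
    do_branches = "branch_lengths" in free_params
    current = engine.log_likelihood()
    if not np.isfinite(current):
        raise ValueError(
            "non-finite log-likelihood at the starting point "
            f"(lnL={current}); check branch lengths and model parameters"
        )
    history = [current]
    converged = False
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        before = current
        if do_branches:
            for node in engine.lin.branch_nodes():
                current = _optimize_branch(engine, node, current, xtol)
        for name in scalar_params:
            current = _optimize_scalar(engine, name, current, xtol)
        history.append(current)
        if current - before < tol:
            converged = True
            break
    engine.lin.write_lengths_back()
    site = engine.site_log_likelihoods()
    return FitResult(model, tree, float(site.sum()), SiteLikelihoods(site),
                     sweeps, converged, history)


def _optimize_branch(engine, node, current, xtol):
    lin = engine.lin
    t0 = lin.lengths[node]

    def objective(logt):
        lin.lengths[node] = np.exp(logt)
        engine.invalidate_branch(node)
        return -engine.log_likelihood()

    lo, hi = np.log(BRANCH_BOUNDS[0]), np.log(BRANCH_BOUNDS[1])
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": xtol})
    if -res.fun > current:
        lin.lengths[node] = float(np.exp(res.x))
        engine.invalidate_branch(node)
        return float(-res.fun)
    lin.lengths[node] = t0
    engine.invalidate_branch(node)
    return current


def _optimize_scalar(engine, name, current, xtol):
    model = engine.model
    v0 = _get_param(model, name)
    lo, hi = _param_bounds(model, name)
    if hi <= lo:
        return current
    log_scale = name not in ("p0", "p1")

    def objective(x):
        _set_param(model, name, np.exp(x) if log_scale else x)
        engine.invalidate_model()
        return -engine.log_likelihood()

    bounds = (np.log(lo), np.log(hi)) if log_scale else (lo, hi)
    res = minimize_scalar(objective, bounds=bounds, method="bounded",
                          options={"xatol": xtol})
    if -res.fun > current:
        best = float(np.exp(res.x)) if log_scale else float(res.x)
        _set_param(model, name, best)
        engine.invalidate_model()
        return float(-res.fun)
    _set_param(model, name, v0)
    engine.invalidate_model()
    return current


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(distance_matrix, labels) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.  Negative branch-length estimates are
    clamped to zero with the deficit moved to the sibling edge (preserving
    the pair's summed distance).  Returns an unrooted tree (trifurcating
    root)."""
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("one label per row required")

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=str(lab))
        nodes.append(nd)
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def get(i, j):
        return dist[(i, j)] if i <= j else dist[(j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best, bi, bj = None, None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qv = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or qv < best - 1e-15:
                    best, bi, bj = qv, i, j
        dij = get(bi, bj)
        li = 0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[bi])
        nodes[bi].edge.length = li
        parent.add_child(nodes[bj])
        nodes[bj].edge.length = lj
        nodes.append(parent)
        k = next_id
        next_id += 1
        for other in active:
            if other in (bi, bj):
                continue
            dist[(min(other, k), max(other, k))] = 0.5 * (
                get(bi, other) + get(bj, other) - dij
            )
        active = [a for a in active if a not in (bi, bj)] + [k]

    i, j, k = active
    li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    root = tree.seed_node
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree.update_taxon_namespace()
    return tree


# ---------------------------------------------------------------------------
# Shimodaira-Hasegawa test
# ---------------------------------------------------------------------------

@dataclass
class SHResult:
    """Per-candidate-topology outcome of the SH test."""

    lnl: np.ndarray          # optimized total lnL per tree
    delta: np.ndarray        # lnL(best) - lnL(tree)
    p_values: np.ndarray
    best_index: int


def sh_test(alignment, candidate_trees, model, n_rell: int = 1000,
            seed=None, optimize_kwargs=None) -> SHResult:
    """Shimodaira-Hasegawa test with RELL bootstrapping.

    Branch lengths are optimized per topology, per-site log-likelihoods are
    resampled (no refitting), centred per tree, and each tree's p-value is
    the fraction of replicates whose centred delta meets or exceeds the
    observed one.  Ties count toward non-rejection; the best tree gets p = 1
    by construction.
    """
    if len(candidate_trees) < 2:
        raise ValueError("need at least 2 candidate topologies")
    optimize_kwargs = dict(optimize_kwargs or {})
    optimize_kwargs.setdefault("free_params", ("branch_lengths",))
    site_mats = []
    for tree in candidate_trees:
        fit = optimize(alignment, tree, model, **optimize_kwargs)
        site_mats.append(fit.site_lnl.values)
    lengths = {len(s) for s in site_mats}
    if len(lengths) != 1:
        raise ValueError("site counts differ across candidate trees")
    site = np.stack(site_mats)          # (n_trees, n_sites)
    totals = site.sum(axis=1)
    best = int(np.argmax(totals))
    delta = totals[best] - totals
    rng = np.random.default_rng(seed)
    n_sites = site.shape[1]
    idx = rng.integers(0, n_sites, size=(n_rell, n_sites))
    boot = site[:, idx].sum(axis=2)     # (n_trees, n_rell)
    centred = boot - boot.mean(axis=1, keepdims=True)
    boot_delta = centred.max(axis=0)[np.newaxis, :] - centred
    p = (boot_delta >= delta[:, np.newaxis] - 1e-12).mean(axis=1)
    return SHResult(totals, delta, p, best)


# ---------------------------------------------------------------------------
# duplication/loss rooting
# ---------------------------------------------------------------------------

@dataclass
class RootingResult:
    """Duplication/loss reconciliation cost for every candidate root edge."""

    costs: list          # (bipartition frozenset, duplications, losses)
    optimal: list        # entries of `costs` minimizing dup + loss

    def best_cost(self) -> tuple[int, int]:
        return self.optimal[0][1], self.optimal[0][2]


def _species_index(species_tree):
    """depth and parent maps for LCA computation on the species tree."""
    depth, parent, by_label = {}, {}, {}
    for nd in species_tree.preorder_node_iter():
        p = nd.parent_node
        parent[id(nd)] = p
        depth[id(nd)] = 0 if p is None else depth[id(p)] + 1
        if nd.is_leaf():
            by_label[nd.taxon.label] = nd
    return depth, parent, by_label


def _species_lca(a, b, depth, parent):
    while id(a) != id(b):
        if depth[id(a)] < depth[id(b)]:
            b = parent[id(b)]
        else:
            a = parent[id(a)]
    return a


def reconcile_costs(rooted_gene_tree, species_tree, label_map=None):
    """Duplications and losses of the LCA reconciliation of a rooted gene
    tree into a species tree.

    A gene node is a duplication when its species mapping equals a child's
    mapping; losses along each gene edge follow the standard path-length
    formula (depth difference, minus one at speciation nodes).
    """
    label_map = label_map or (lambda x: x)
    depth, parent, by_label = _species_index(species_tree)
    mapping = {}
    dups = 0
    losses = 0
    for nd in rooted_gene_tree.postorder_node_iter():
        if nd.is_leaf():
            sp = label_map(nd.taxon.label)
            if sp not in by_label:
                raise ValueError(
                    f"gene-tree leaf {nd.taxon.label!r} maps to unknown "
                    f"species {sp!r}"
                )
            mapping[id(nd)] = by_label[sp]
            continue
        kids = nd.child_nodes()
        m = mapping[id(kids[0])]
        for c in kids[1:]:
            m = _species_lca(m, mapping[id(c)], depth, parent)
        mapping[id(nd)] = m
        is_dup = any(id(mapping[id(c)]) == id(m) for c in kids)
        if is_dup:
            dups += 1
        for c in kids:
            gap = depth[id(mapping[id(c)])] - depth[id(m)]
            losses += gap if is_dup else gap - 1
    return dups, losses


def root_by_duplication_loss(gene_tree, species_tree, label_map=None) -> RootingResult:
    """Score every candidate root edge of an unrooted gene tree by the
    duplication + loss cost (unit costs) of its LCA reconciliation with the
    species tree; return all cost-minimizing root edges."""
    base = clone_tree(gene_tree)
    if len(base.seed_node.child_nodes()) == 2:
        base.deroot()
    n_edges = sum(1 for e in base.preorder_edge_iter() if e.head_node.parent_node)
    all_taxa = frozenset(l.taxon.label for l in base.leaf_node_iter())
    costs = []
    for k in range(n_edges):
        work = clone_tree(base)
        edges = [e for e in work.preorder_edge_iter() if e.head_node.parent_node]
        edge = edges[k]
        bipart = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        if edge.length is None:
            edge.length = 1.0
        work.reroot_at_edge(edge, update_bipartitions=False)
        d, l = reconcile_costs(work, species_tree, label_map=label_map)
        canon = bipart if min(all_taxa) not in bipart else all_taxa - bipart
        costs.append((canon, d, l))
    best = min(d + l for _, d, l in costs)
    optimal = [c for c in costs if c[1] + c[2] == best]
    return RootingResult(costs, optimal)
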
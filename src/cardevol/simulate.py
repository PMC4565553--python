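"""Generators for every input the pipeline consumes.

Random trees, protein alignments evolved under LG(+F)+gamma with true
ancestral states recorded, in-frame codon alignments under neutral / sites /
branch-site-released omega regimes, and biolayer-interferometry-like binding
traces with 1:1 Langmuir kinetics plus Gaussian noise and optional baseline
drift.  Every generator is deterministic under a fixed seed.

The default "CARD family" fixture emulates the scale of a five-subfamily
domain alignment (~90-100 residues, tens of taxa on one shared tree); it is
a synthetic stand-in, not a transcription of any published data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignment import CodonAlignment, ProteinAlignment
from .io import SequenceRecord, TraceTable
from .models import (
    AA_ORDER,
    CODONS,
    CodonModel,
    ProteinModel,
    ReversibleEigen,
    build_rate_matrix,
    lg_model,
)
from .treeutil import LinearTree, find_branch_nodes, parse_tree

__all__ = [
    "random_tree",
    "SimulatedAlignment",
    "simulate_protein_alignment",
    "simulate_codon_alignment",
    "KineticsSimSpec",
    "simulate_kinetics",
    "card_family_fixture",
]


def random_tree(n_taxa: int, total_length: float = 1.0, seed=None,
                taxon_labels=None) -> dendropy.Tree:
    """Random rooted binary tree by iterative random joining, with
    exponential branch lengths rescaled so the branch-length sum equals
    ``total_length``."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    if taxon_labels is None:
        taxon_labels = [f"t{i + 1}" for i in range(n_taxa)]
    if len(taxon_labels) != n_taxa:
        raise ValueError("one label per taxon required")
    subtrees = list(taxon_labels)
    # one pending branch length per live subtree
    lengths = list(rng.exponential(1.0, size=n_taxa))
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        merged = f"({subtrees[i]}:{lengths[i]:.10g},{subtrees[j]}:{lengths[j]:.10g})"
        for k in sorted((i, j), reverse=True):
            subtrees.pop(k)
            lengths.pop(k)
        subtrees.append(merged)
        lengths.append(float(rng.exponential(1.0)))
    tree = parse_tree(subtrees[0] + ";")
    lin = LinearTree(tree)
    scale = total_length / lin.total_length()
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= scale
    return tree


@dataclass
class SimulatedAlignment:
    """An alignment plus the simulation truth: ancestral states per internal
    node (keyed by clade) and the per-site rate category or omega class."""

    alignment: object
    ancestral: dict
    site_assignments: np.ndarray


def _evolve_states(lin: LinearTree, eig_by_branch, root_freqs, site_rates,
                   n_sites, rng):
    """Sample states down the tree.  ``eig_by_branch(node, cat)`` returns the
    eigensystem for a branch; ``site_rates`` gives each site's category index
    and the per-category rate multiplier is folded into the caller's
    transition call."""
    n_states = len(root_freqs)
    states = np.empty((lin.n_nodes, n_sites), dtype=np.int32)
    states[lin.root] = rng.choice(n_states, size=n_sites, p=root_freqs)
    for i in range(lin.n_nodes - 1, -1, -1):  # preorder
        for c in lin.children[i]:
            child = np.empty(n_sites, dtype=np.int32)
            for cat in np.unique(site_rates):
                mask = site_rates == cat
                p = eig_by_branch(c, int(cat))
                cdf = np.cumsum(p[states[i, mask]], axis=1)
                u = rng.random(mask.sum())
                child[mask] = (u[:, np.newaxis] > cdf).sum(axis=1)
            states[c] = child
    return states


def simulate_protein_alignment(tree, model: ProteinModel, n_sites: int,
                               seed=None, deletion=None) -> SimulatedAlignment:
    """Evolve a protein alignment along ``tree`` under ``model``.

    The root is drawn from the stationary frequencies; each site is assigned
    one discrete-gamma category.  True states at every internal node are
    recorded for error scoring.  ``deletion``, if given, is a
    ``(clade, start, stop)`` triple (0-based half-open columns) masking a
    contiguous block to gaps in that clade's leaves, to exercise indel
    parsimony.
    """
    rng = np.random.default_rng(seed)
    lin = LinearTree(tree)
    if np.any(lin.lengths < 0):
        raise ValueError("branch lengths must be nonnegative")
    q = build_rate_matrix(model)
    eig = ReversibleEigen(q, model.frequencies)
    rates = model.rate_multipliers()
    site_cats = rng.integers(len(rates), size=n_sites)
    cache = {}

    def branch_eig(node, cat):
        key = (node, cat)
        if key not in cache:
            cache[key] = eig.transition(lin.lengths[node] * rates[cat])
        return cache[key]

    states = _evolve_states(lin, branch_eig, model.frequencies, site_cats,
                            n_sites, rng)
    records = []
    for i in lin.leaf_indices:
        seq = "".join(AA_ORDER[s] for s in states[i])
        records.append(SequenceRecord(lin.labels[i], seq))
    if deletion is not None:
        clade, start, stop = deletion
        clade = frozenset(clade)
        records = [
            SequenceRecord(
                r.id,
                r.seq[:start] + "-" * (stop - start) + r.seq[stop:]
                if r.id in clade else r.seq,
            )
            for r in records
        ]
    ancestral = {lin.leafsets[i]: states[i].copy()
                 for i in lin.internal_indices}
    return SimulatedAlignment(ProteinAlignment(records), ancestral, site_cats)


def simulate_codon_alignment(tree, model: CodonModel, n_codons: int,
                             regime: str = "neutral", foreground=None,
                             seed=None) -> SimulatedAlignment:
    """Evolve an in-frame codon alignment along ``tree``.

    Regimes:

    - ``neutral``: omega = 1 at all sites on all branches.
    - ``sites``: the model's two-class sites mixture (p0 of sites at omega0,
      the rest neutral) on every branch.
    - ``branch_sites_released``: the sites mixture on background branches,
      with all sites released to omega = 1 on the foreground branch.

    ``model`` supplies kappa, codon frequencies and (for the sites regimes)
    p0/omega0.  Per-site class assignments are recorded; no stop codons can
    arise (the state space is the 61 sense codons).
    """
    rng = np.random.default_rng(seed)
    lin = LinearTree(tree)
    if regime not in ("neutral", "sites", "branch_sites_released"):
        raise ValueError(f"unknown regime {regime!r}")
    if regime == "neutral":
        sim_model = CodonModel.one_ratio(1.0, kappa=model.kappa,
                                         codon_freqs=model.codon_freqs)
    else:
        p = model.params
        if "p0" not in p or "omega0" not in p:
            raise ValueError(
                f"regime {regime!r} needs a sites model with p0 and omega0"
            )
        sim_model = CodonModel.sites(p["p0"], p["omega0"], kappa=model.kappa,
                                     codon_freqs=model.codon_freqs)
    fg_nodes = frozenset()
    if regime == "branch_sites_released":
        if foreground is None:
            raise ValueError("branch_sites_released regime needs a foreground branch")
        fg_nodes = frozenset(find_branch_nodes(lin, foreground))
    mats = sim_model.rate_matrices()
    weights = np.array([w for w, _, _ in mats])
    site_classes = rng.choice(len(mats), size=n_codons, p=weights / weights.sum())
    eigs_bg = [ReversibleEigen(qb, sim_model.codon_freqs) for _, qb, _ in mats]
    if fg_nodes:
        # released foreground: omega = 1 for every site, on the same time
        # scale as the background mixture
        from .models import codon_rate_matrix

        raw_neutral = codon_rate_matrix(sim_model.kappa, 1.0,
                                        sim_model.codon_freqs, normalize=False)
        raw = [codon_rate_matrix(sim_model.kappa, sc.omega_background,
                                 sim_model.codon_freqs, normalize=False)
               for sc in sim_model.site_classes()]
        scale = sum(
            sc.proportion * -(sim_model.codon_freqs * np.diag(q)).sum()
            for sc, q in zip(sim_model.site_classes(), raw)
        )
        eig_fg = ReversibleEigen(raw_neutral / scale, sim_model.codon_freqs)
    cache = {}

    def branch_eig(node, cat):
        key = (node, cat)
        if key not in cache:
            if node in fg_nodes:
                cache[key] = eig_fg.transition(lin.lengths[node])
            else:
                cache[key] = eigs_bg[cat].transition(lin.lengths[node])
        return cache[key]

    states = _evolve_states(lin, branch_eig, sim_model.codon_freqs,
                            site_classes, n_codons, rng)
    records = []
    for i in lin.leaf_indices:
        seq = "".join(CODONS[s] for s in states[i])
        records.append(SequenceRecord(lin.labels[i], seq))
    ancestral = {lin.leafsets[i]: states[i].copy()
                 for i in lin.internal_indices}
    return SimulatedAlignment(CodonAlignment(records), ancestral, site_classes)


# ---------------------------------------------------------------------------
# binding kinetics
# ---------------------------------------------------------------------------

def _default_concentrations() -> np.ndarray:
    return np.logspace(-9, -4, 7)


@dataclass
class KineticsSimSpec:
    """Parameters of the 1:1 Langmuir binding-trace generator.

    ``Kd_true`` is the equilibrium dissociation constant (M); ``kon``
    (1/(M s)) sets the association rate and fixes ``koff = kon * Kd_true``.
    Seven log-spaced analyte concentrations across 1 nM - 100 uM, three
    replicates and a 0-concentration blank per replicate mirror a
    plate-based biolayer-interferometry run; the 1 s sample interval keeps
    synthetic traces small while leaving > 500 association samples for the
    steady-state averaging rule.
    """

    Kd_true: float = 3e-8
    kon: float = 5e5
    Rmax: float = 1.0
    concentrations: np.ndarray = field(default_factory=_default_concentrations)
    noise_sd: float = 0.02
    drift: float = 0.0
    n_replicates: int = 3
    sample_interval: float = 1.0
    phase_duration: float = 600.0
    seed: int | None = None

    def __post_init__(self):
        self.concentrations = np.sort(np.asarray(self.concentrations, float))
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if self.Kd_true <= 0 or self.kon <= 0 or self.Rmax <= 0:
            raise ValueError("Kd_true, kon and Rmax must be positive")

    @property
    def koff(self) -> float:
        return self.kon * self.Kd_true


def simulate_kinetics(spec: KineticsSimSpec) -> TraceTable:
    """Association/dissociation traces under 1:1 Langmuir binding.

    Association: ``R(t) = Rmax*C/(C+Kd) * (1 - exp(-(kon*C+koff) t))
    + drift*t + noise``; dissociation: exponential decay of the association
    end level at rate ``koff`` plus noise.  A blank (0-concentration) trace
    of pure drift + noise is emitted per replicate for blank correction.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.phase_duration + 1e-9, spec.sample_interval)
    rows = []
    koff = spec.koff
    for rep in range(1, spec.n_replicates + 1):
        for conc in np.concatenate([[0.0], spec.concentrations]):
            if conc > 0:
                req = spec.Rmax * conc / (conc + spec.Kd_true)
                kobs = spec.kon * conc + koff
                assoc = req * (1.0 - np.exp(-kobs * t)) + spec.drift * t
                r_end = req * (1.0 - np.exp(-kobs * t[-1]))
                dissoc = r_end * np.exp(-koff * t)
            else:
                assoc = spec.drift * t
                dissoc = np.zeros_like(t)
            for phase, clean in (("association", assoc), ("dissociation", dissoc)):
                noise = (rng.normal(0.0, spec.noise_sd, size=t.shape)
                         if spec.noise_sd > 0 else 0.0)
                sig = clean + noise
                rows.append(pd.DataFrame({
                    "time": t,
                    "signal": sig,
                    "concentration_M": conc,
                    "replicate": rep,
                    "phase": phase,
                }))
    return TraceTable(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# the synthetic CARD-family fixture
# ---------------------------------------------------------------------------

def card_family_fixture(seed: int = 0, n_groups: int = 5,
                        taxa_per_group: int = 10, n_sites: int = 95,
                        stem_length: float = 0.8, group_depth: float = 0.5,
                        alpha: float = 1.0):
    """A five-subfamily protein-domain dataset on one shared tree.

    Each group hangs off the root on a stem of ``stem_length`` expected
    substitutions/site, with a random within-group subtree rescaled so the
    mean root-to-tip depth inside the group is ``group_depth``.  Sequences
    evolve under LG + gamma(``alpha``).

    Returns ``(alignment, tree, groups)`` with ``groups`` mapping group name
    to its taxon labels.
    """
    rng = np.random.default_rng(seed)
    groups = {}
    parts = []
    for g in range(1, n_groups + 1):
        labels = [f"G{g}_t{i + 1}" for i in range(taxa_per_group)]
        groups[f"G{g}"] = labels
        sub = random_tree(taxa_per_group, total_length=1.0,
                          seed=int(rng.integers(2 ** 31)),
                          taxon_labels=labels)
        lin = LinearTree(sub)
        depths = _mean_root_to_tip(lin)
        scale = group_depth / depths
        for nd in sub.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length *= scale
        newick = sub.as_string(schema="newick", suppress_rooting=True,
                               unquoted_underscores=True).strip().rstrip(";")
        parts.append(f"{newick}:{stem_length:.10g}")
    tree = parse_tree("(" + ",".join(parts) + ");")
    model = lg_model(alpha=alpha)
    sim = simulate_protein_alignment(tree, model, n_sites,
                                     seed=int(rng.integers(2 ** 31)))
    return sim.alignment, tree, groups


def _mean_root_to_tip(lin: LinearTree) -> float:
    depth = np.zeros(lin.n_nodes)
    for i in range(lin.n_nodes - 1, -1, -1):
        for c in lin.children[i]:
            depth[c] = depth[i] + lin.lengths[c]
    return float(np.mean([depth[i] for i in lin.leaf_indices]))
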
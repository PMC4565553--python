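"""Marginal ancestral sequence reconstruction and its summaries.

Empirical-Bayes marginal reconstruction on a fixed topology, integration of
reconstructions over a weighted tree set (clades matched across topologies by
descendant-leaf-set equality), Fitch parsimony reconstruction of indel
presence/absence, posterior-confidence summaries, and a chi-square check of
amino-acid compositional stationarity across sequence groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .alignment import ProteinAlignment
from .models import AA_INDEX, AA_ORDER
from .phylo import LikelihoodEngine
from .treeutil import LinearTree

__all__ = [
    "DEFAULT_BIOCHEM_CLASSES",
    "residue_class_array",
    "MarginalReconstruction",
    "marginal_reconstruct",
    "integrate_over_trees",
    "parsimony_indels",
    "confidence_summary",
    "stationarity_test",
]

#: default 7-class biochemical grouping of the 20 residues
DEFAULT_BIOCHEM_CLASSES = {
    "aliphatic": "AVLIMC",
    "aromatic": "FWY",
    "polar": "STNQ",
    "acidic": "DE",
    "basic": "KRH",
    "glycine": "G",
    "proline": "P",
}


def residue_class_array(classes=None) -> np.ndarray:
    """Class index per residue (in ``AA_ORDER``); validates that the classes
    partition the 20 residues."""
    classes = classes or DEFAULT_BIOCHEM_CLASSES
    out = np.full(20, -1, dtype=int)
    for k, (name, members) in enumerate(classes.items()):
        for ch in members:
            idx = AA_INDEX[ch]
            if out[idx] != -1:
                raise ValueError(f"residue {ch} assigned to two classes")
            out[idx] = k
    if np.any(out < 0):
        missing = [AA_ORDER[i] for i in np.where(out < 0)[0]]
        raise ValueError(f"residues not covered by any class: {missing}")
    return out


@dataclass
class MarginalReconstruction:
    """Per-site posterior state distributions at one ancestral node.

    The node is identified by the frozenset of its descendant leaf labels.
    MAP ties are broken by the fixed residue order (``AA_ORDER``) for
    determinism.  ``presence`` flags (from indel parsimony) mark which sites
    existed in the ancestor; absent sites are excluded from summaries.
    """

    clade: frozenset
    posteriors: np.ndarray                 # (n_sites, n_states)
    presence: np.ndarray = None            # (n_sites,) bool
    map_indices: np.ndarray = field(init=False)
    map_posterior: np.ndarray = field(init=False)
    alt_indices: np.ndarray = field(init=False)
    alt_posterior: np.ndarray = field(init=False)

    def __post_init__(self):
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if self.presence is None:
            self.presence = np.ones(self.posteriors.shape[0], dtype=bool)
        self.presence = np.asarray(self.presence, dtype=bool)
        self._refresh()

    def _refresh(self):
        p = self.posteriors
        self.map_indices = p.argmax(axis=1)         # first max = AA_ORDER tie-break
        self.map_posterior = p[np.arange(len(p)), self.map_indices]
        masked = p.copy()
        masked[np.arange(len(p)), self.map_indices] = -1.0
        self.alt_indices = masked.argmax(axis=1)
        self.alt_posterior = p[np.arange(len(p)), self.alt_indices]

    @property
    def n_sites(self) -> int:
        return self.posteriors.shape[0]

    def map_sequence(self, alphabet: str = AA_ORDER) -> str:
        """MAP sequence with gaps at absent sites."""
        return "".join(
            alphabet[i] if pres else "-"
            for i, pres in zip(self.map_indices, self.presence)
        )

    def to_frame(self, alphabet: str = AA_ORDER) -> pd.DataFrame:
        """Per-site posterior table (1-based site coordinates)."""
        df = pd.DataFrame(self.posteriors, columns=list(alphabet))
        df.insert(0, "site", np.arange(1, self.n_sites + 1))
        df["map_state"] = [alphabet[i] for i in self.map_indices]
        df["map_posterior"] = self.map_posterior
        df["present"] = self.presence
        return df


def marginal_reconstruct(alignment, tree, model, foreground=None):
    """Marginal (empirical-Bayes) ancestral reconstruction at every internal
    node of a rooted tree: posterior state distributions given the tip data,
    summing over rate categories.

    Returns a dict keyed by clade (descendant leaf set).
    """
    engine = LikelihoodEngine(alignment, tree, model, foreground=foreground)
    node_posteriors = engine.marginal_posteriors()
    out = {}
    for i, post in node_posteriors.items():
        clade = engine.lin.leafsets[i]
        out[clade] = MarginalReconstruction(clade, post)
    return out


def integrate_over_trees(reconstructions, weights, target_clade):
    """Average reconstructions of one clade across a weighted tree set.

    ``reconstructions`` is a sequence of per-tree reconstruction dicts (as
    returned by :func:`marginal_reconstruct`).  The posterior at each site is
    the weight-normalized average over trees that contain the clade; the
    returned support fraction is the total weight of those trees.
    """
    target = frozenset(target_clade)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    num = None
    w_in = 0.0
    presence_num = None
    for recs, w in zip(reconstructions, weights):
        rec = recs.get(target) if isinstance(recs, dict) else (
            recs if recs.clade == target else None
        )
        if rec is None:
            continue
        w_in += w
        contrib = w * rec.posteriors
        num = contrib if num is None else num + contrib
        pres = w * rec.presence.astype(float)
        presence_num = pres if presence_num is None else presence_num + pres
    if num is None:
        raise ValueError(
            f"clade {sorted(target)} present in no tree of the set"
        )
    posteriors = num / w_in
    presence = (presence_num / w_in) >= 0.5
    integrated = MarginalReconstruction(target, posteriors, presence)
    return integrated, float(w_in)


# ---------------------------------------------------------------------------
# indel parsimony
# ---------------------------------------------------------------------------

def _fitch_presence(lin: LinearTree, leaf_states: dict[str, np.ndarray]):
    """Fitch parsimony on 0/1 presence coding, per site.  Ambiguous states
    are resolved toward presence (root tie rule), children inherit the
    parent's state when their Fitch set allows it."""
    n_sites = next(iter(leaf_states.values())).shape[0]
    # Fitch sets encoded as bitmasks: 1 = {absent}, 2 = {present}, 3 = both
    sets = np.zeros((lin.n_nodes, n_sites), dtype=np.int8)
    for i in range(lin.n_nodes):
        kids = lin.children[i]
        if not kids:
            st = leaf_states[lin.labels[i]]
            sets[i] = np.where(st > 0, 2, 1)
            continue
        inter = np.full(n_sites, 3, dtype=np.int8)
        union = np.zeros(n_sites, dtype=np.int8)
        for c in kids:
            inter &= sets[c]
            union |= sets[c]
        sets[i] = np.where(inter > 0, inter, union)
    final = np.zeros((lin.n_nodes, n_sites), dtype=np.int8)
    order = list(range(lin.n_nodes - 1, -1, -1))  # preorder
    for i in order:
        if i == lin.root:
            final[i] = np.where(sets[i] & 2, 1, 0)  # ambiguity -> presence
            continue
        p = lin.parent[i]
        parent_bit = np.where(final[p] > 0, 2, 1)
        keep_parent = (sets[i] & parent_bit) > 0
        own = np.where(sets[i] & 2, 1, 0)           # ties -> presence
        final[i] = np.where(keep_parent, final[p], own)
    return final


def parsimony_indels(alignment: ProteinAlignment, tree_set, weights=None):
    """Ancestral presence/absence of every alignment column by Fitch
    parsimony, weight-averaged over a tree set.

    ``tree_set`` may be a ``WeightedTreeSet`` or a list of trees with
    explicit ``weights``.  Per clade, the presence probability is the
    weighted fraction of trees (containing that clade) in which the Fitch
    state is presence; the call is presence iff the probability is >= 0.5.

    Returns ``{clade: (probability_array, call_array)}``.
    """
    if weights is None:
        trees = [t for t, _ in tree_set]
        weights = np.array([w for _, w in tree_set], dtype=float)
    else:
        trees = list(tree_set)
        weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    presence = alignment.presence_matrix()
    leaf_states = {rec.id: presence[i] for i, rec in enumerate(alignment.records)}
    acc: dict[frozenset, np.ndarray] = {}
    wsum: dict[frozenset, float] = {}
    for tree, w in zip(trees, weights):
        lin = LinearTree(tree)
        final = _fitch_presence(lin, leaf_states)
        for clade, i in lin.clades().items():
            acc[clade] = acc.get(clade, 0.0) + w * final[i].astype(float)
            wsum[clade] = wsum.get(clade, 0.0) + w
    out = {}
    for clade in acc:
        prob = acc[clade] / wsum[clade]
        out[clade] = (prob, prob >= 0.5)
    return out


# ---------------------------------------------------------------------------
# confidence summaries
# ---------------------------------------------------------------------------

def confidence_summary(reconstructions, thresholds=(0.95, 0.90, 0.80),
                       alt_threshold: float = 0.3, classes=None) -> dict:
    """Summaries of reconstruction confidence, per node and pooled.

    For present sites only: the fraction of sites whose MAP posterior
    exceeds each threshold; the count/fraction of ambiguous sites (second-
    best posterior above ``alt_threshold``); and, among ambiguous sites, the
    fraction whose alternative residue falls in the same biochemical class
    as the MAP residue.
    """
    if isinstance(reconstructions, MarginalReconstruction):
        reconstructions = {reconstructions.clade: reconstructions}
    if not reconstructions:
        raise ValueError("empty reconstruction set")
    class_of = residue_class_array(classes)
    thresholds = sorted(thresholds, reverse=True)
    per_node = {}
    pool_map, pool_alt, pool_same = [], [], []
    for clade, rec in reconstructions.items():
        pres = rec.presence
        if pres.sum() == 0:
            continue
        mp = rec.map_posterior[pres]
        ap = rec.alt_posterior[pres]
        ambiguous = ap > alt_threshold
        same = (class_of[rec.map_indices[pres]] ==
                class_of[rec.alt_indices[pres]])
        per_node[clade] = {
            "n_sites": int(pres.sum()),
            "above_threshold": {
                t: float((mp > t).mean()) for t in thresholds
            },
            "n_ambiguous": int(ambiguous.sum()),
            "fraction_ambiguous": float(ambiguous.mean()),
            "fraction_same_class": (
                float(same[ambiguous].mean()) if ambiguous.any() else float("nan")
            ),
        }
        pool_map.append(mp)
        pool_alt.append(ap)
        pool_same.append(same)
    if not per_node:
        raise ValueError("no present sites in any reconstruction")
    mp = np.concatenate(pool_map)
    ap = np.concatenate(pool_alt)
    same = np.concatenate(pool_same)
    ambiguous = ap > alt_threshold
    pooled = {
        "n_sites": int(mp.size),
        "above_threshold": {t: float((mp > t).mean()) for t in thresholds},
        "n_ambiguous": int(ambiguous.sum()),
        "fraction_ambiguous": float(ambiguous.mean()),
        "fraction_same_class": (
            float(same[ambiguous].mean()) if ambiguous.any() else float("nan")
        ),
    }
    return {"per_node": per_node, "pooled": pooled}


# ---------------------------------------------------------------------------
# compositional stationarity
# ---------------------------------------------------------------------------

def stationarity_test(groups) -> pd.DataFrame:
    """Chi-square test of each group's residue composition against the
    pooled composition across all groups.

    ``groups`` maps group name to either sequences (records/strings, gaps
    excluded from counts) or a precomputed count vector.  Expected counts
    come from pooled frequencies; df = (number of states) - 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = {}
    for name, val in groups.items():
        is_counts = isinstance(val, np.ndarray) or (
            isinstance(val, (list, tuple)) and len(val) > 0
            and isinstance(val[0], (int, float, np.number))
        )
        if is_counts:
            counts[name] = np.asarray(val, dtype=float)
        else:
            c = np.zeros(20)
            for rec in val:
                seq = getattr(rec, "seq", None)
                if seq is None:
                    seq = rec[1] if isinstance(rec, tuple) else rec
                for ch in seq.upper():
                    idx = AA_INDEX.get(ch)
                    if idx is not None:
                        c[idx] += 1
            counts[name] = c
    sizes = {len(c) for c in counts.values()}
    if len(sizes) != 1:
        raise ValueError("count vectors must share one alphabet")
    k = sizes.pop()
    pooled = sum(counts.values())
    pooled_freq = pooled / pooled.sum()
    rows = []
    for name, c in counts.items():
        total = c.sum()
        if total == 0:
            raise ValueError(f"group {name!r} has no residues")
        expected = total * pooled_freq
        ok = expected > 0
        stat = float((((c - expected) ** 2)[ok] / expected[ok]).sum())
        df = k - 1
        rows.append(
            {"group": name, "n": int(total), "statistic": stat, "df": df,
             "p_value": float(chi2.sf(stat, df))}
        )
    return pd.DataFrame(rows)
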
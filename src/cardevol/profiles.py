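"""Subfamily profile HMMs, their Kullback-Leibler clustering, and the
pairwise sequence-similarity network.

Profile HMMs are built per subfamily from column slices of one master
alignment, so all HMMs share a match-state coordinate system and can be
compared positionwise.  The distance between two HMMs is the mean symmetrized
Kullback-Leibler divergence of their match emissions; neighbor joining on
the distance matrix clusters the subfamilies.  The similarity network scores
all sequence pairs by Smith-Waterman local alignment (BLOSUM62) with
BLAST-style e-values and keeps edges up to an e-value cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .models import AA_INDEX, AA_ORDER
from .phylo import neighbor_joining

__all__ = [
    "ProfileHMM",
    "build_hmm",
    "hmm_distance",
    "hmm_distance_matrix",
    "hmm_tree",
    "SimilarityNetwork",
    "similarity_network",
    "export_network",
    "sw_score",
    "blast_evalue",
]

#: published gapped BLOSUM62 Karlin-Altschul constants (gap open 11, extend 1)
BLAST_LAMBDA = 0.267
BLAST_K = 0.041

MATCH_PSEUDOCOUNT = 0.2
TRANSITION_PSEUDOCOUNT = 1.0


@dataclass
class ProfileHMM:
    """A profile hidden Markov model over match/insert/delete states.

    ``match_emissions[k]`` is the emission distribution of match state k
    (over ``AA_ORDER``); ``match_columns`` records which master-alignment
    columns (0-based) became match states.  Transition distributions are
    stored per source state; every distribution sums to 1.
    """

    group: str
    match_columns: np.ndarray
    match_emissions: np.ndarray           # (L, 20)
    trans_match: np.ndarray               # (L+1, 3): M->M, M->I, M->D
    trans_insert: np.ndarray              # (L+1, 2): I->M, I->I
    trans_delete: np.ndarray              # (L, 2):   D->M, D->D

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]


def build_hmm(sub_alignment, group: str = "") -> ProfileHMM:
    """Build a profile HMM from an aligned subfamily.

    Columns with at least 50% non-gap characters become match states.
    Match emissions are column counts plus a 0.2 pseudocount per residue,
    normalized; transitions are counted from each sequence's path through
    the match/insert/delete architecture with +1 pseudocounts.
    """
    records = list(sub_alignment)
    if len(records) < 2:
        raise ValueError("need at least 2 aligned sequences to build an HMM")
    seqs = [r.seq.upper() for r in records]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned")
    n_cols = len(seqs[0])
    n_seqs = len(seqs)
    occupancy = np.array(
        [sum(s[c] != "-" for s in seqs) / n_seqs for c in range(n_cols)]
    )
    match_cols = np.where(occupancy >= 0.5)[0]
    if len(match_cols) == 0:
        raise ValueError("alignment has no match columns (all too gappy)")
    L = len(match_cols)
    emissions = np.full((L, 20), MATCH_PSEUDOCOUNT)
    for k, c in enumerate(match_cols):
        for s in seqs:
            idx = AA_INDEX.get(s[c])
            if idx is not None:
                emissions[k, idx] += 1.0
    emissions /= emissions.sum(axis=1, keepdims=True)

    tm = np.full((L + 1, 3), TRANSITION_PSEUDOCOUNT)
    ti = np.full((L + 1, 2), TRANSITION_PSEUDOCOUNT)
    td = np.full((L, 2), TRANSITION_PSEUDOCOUNT)
    match_set = set(match_cols.tolist())
    for s in seqs:
        state, k = "M", 0          # begin state is M_0
        for c in range(n_cols):
            if c in match_set:
                nxt = "M" if s[c] != "-" else "D"
                if state == "M":
                    tm[k, 0 if nxt == "M" else 2] += 1
                elif state == "I":
                    ti[k, 0] += 1
                else:
                    td[k - 1, 0 if nxt == "M" else 1] += 1
                k += 1
                state = nxt if nxt == "M" else "D"
            elif s[c] != "-":
                if state == "M":
                    tm[k, 1] += 1
                elif state == "I":
                    ti[k, 1] += 1
                # deletes do not emit; D->I transitions are not modelled
                state = "I" if state != "D" else "D"
    tm /= tm.sum(axis=1, keepdims=True)
    ti /= ti.sum(axis=1, keepdims=True)
    td /= td.sum(axis=1, keepdims=True)
    return ProfileHMM(group, match_cols, emissions, tm, ti, td)


def hmm_distance(h1: ProfileHMM, h2: ProfileHMM) -> float:
    """Mean positionwise symmetrized Kullback-Leibler divergence between
    match emissions: 0.5*[KL(p||q) + KL(q||p)], averaged over match states.
    Transition probabilities are excluded."""
    if h1.length != h2.length:
        raise ValueError(
            f"HMM match lengths differ ({h1.length} vs {h2.length}); build "
            "all HMMs from column slices of one master alignment"
        )
    p, q = h1.match_emissions, h2.match_emissions

    def kl(a, b):
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(a > 0, a * np.log(a / b), 0.0)
        return terms.sum(axis=1)       # 0*log(0) := 0; a>0, b=0 -> inf

    return float(0.5 * (kl(p, q) + kl(q, p)).mean())


def hmm_distance_matrix(hmms) -> np.ndarray:
    n = len(hmms)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hmm_distance(hmms[i], hmms[j])
    return d


def hmm_tree(hmms, labels=None):
    """Neighbor-joining tree of subfamily HMMs from their pairwise
    Kullback-Leibler distances."""
    if len(hmms) < 3:
        raise ValueError("need at least 3 HMMs")
    if labels is None:
        labels = [h.group or f"hmm{i + 1}" for i, h in enumerate(hmms)]
    return neighbor_joining(hmm_distance_matrix(hmms), labels)


# ---------------------------------------------------------------------------
# similarity network
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # a gap of length k costs 11 + k (BLAST convention)
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def sw_score(seq_a: str, seq_b: str) -> float:
    """Smith-Waterman local alignment score (BLOSUM62, gap open 11,
    extend 1).  Gap characters are removed before scoring."""
    a = seq_a.replace("-", "").upper()
    b = seq_b.replace("-", "").upper()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return float(_aligner().score(a, b))


def blast_evalue(score: float, m: int, n: int) -> float:
    """Karlin-Altschul e-value K*m*n*exp(-lambda*S) with published gapped
    BLOSUM62 constants."""
    return float(BLAST_K * m * n * math.exp(-BLAST_LAMBDA * score))


@dataclass
class SimilarityNetwork:
    """All-vs-all local-alignment similarity graph (nodes: sequences,
    edges kept iff e-value <= cutoff)."""

    graph: nx.Graph
    evalue_cutoff: float

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"seq1": u, "seq2": v, "score": d["score"], "evalue": d["evalue"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows).sort_values("evalue", ignore_index=True) \
            if rows else pd.DataFrame(columns=["seq1", "seq2", "score", "evalue"])


def similarity_network(records, evalue_cutoff: float = 1e-3,
                       groups: dict | None = None) -> SimilarityNetwork:
    """Score all unordered sequence pairs by Smith-Waterman local alignment
    and keep edges with e-value at or below the cutoff.

    ``groups`` optionally maps sequence id to a subfamily label stored as a
    node attribute (for downstream coloring/layout in external viewers).
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    aligner = _aligner()
    ungapped = {r.id: r.seq.replace("-", "").upper() for r in records}
    for rid, s in ungapped.items():
        if not s:
            raise ValueError(f"sequence {rid!r} is empty after removing gaps")
    g = nx.Graph()
    for r in records:
        g.add_node(r.id, group=(groups or {}).get(r.id, ""))
    ids = [r.id for r in records]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ungapped[ids[i]], ungapped[ids[j]]
            score = float(aligner.score(a, b))
            ev = blast_evalue(score, len(a), len(b))
            if ev <= evalue_cutoff:
                g.add_edge(ids[i], ids[j], score=score, evalue=ev)
    return SimilarityNetwork(g, evalue_cutoff)


def export_network(network: SimilarityNetwork, graphml_path=None,
                   edge_list_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(network.graph, graphml_path)
    if edge_list_path is not None:
        network.edges_frame().to_csv(edge_list_path, sep="\t", index=False)
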
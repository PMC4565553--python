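"""Tests for protein-coding adaptation and gene conversion.

The branch-site likelihood-ratio test compares branch-site model A (a class
of sites with omega2 >= 1 on one foreground branch) against its null
(omega2 = 1), with the statistic referred to a chi-square with 1 df and a
Bonferroni correction across tested branches.  The gene-conversion screen
looks for unusually long runs of agreement between sequence pairs at
polymorphic alignment columns and calibrates them by permuting column order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .alignment import CodonAlignment
from .models import CodonModel
from .phylo import optimize

__all__ = [
    "LRTResult",
    "branch_sites_lrt",
    "bonferroni",
    "ConversionFragment",
    "gene_conversion_scan",
]


@dataclass
class LRTResult:
    """Outcome of one branch-site likelihood-ratio test."""

    branch: frozenset
    lnl_alt: float
    lnl_null: float
    statistic: float
    df: int
    p_raw: float
    p_bonferroni: float
    params: dict

    @property
    def significant(self) -> bool:
        return self.p_bonferroni < 0.05


def branch_sites_lrt(codon_alignment: CodonAlignment, tree, foreground,
                     m_tests: int = 1, kappa: float = 2.0, codon_freqs=None,
                     fit_branch_lengths: bool = True,
                     boundary_mixture: bool = False,
                     tol: float = 1e-4, xtol: float = 1e-3,
                     max_sweeps: int = 30) -> LRTResult:
    """Branch-site test of positive selection on one foreground branch.

    Stage 1 (optional, default on): branch lengths and kappa are estimated
    once under a one-ratio model and then fixed — the standard two-step
    practice for branch-site scans.  Stage 2: the model-A null (omega2 = 1)
    is fitted, then the alternative starting from the null's estimates, so
    the nesting inequality lnL_alt >= lnL_null holds by construction.  The
    statistic 2*(lnL_alt - lnL_null) (clamped at 0) is referred to
    chi-square df = 1; ``boundary_mixture=True`` instead uses the 50:50
    mixture of chi-square(1) and a point mass at zero, which halves the
    p-value of positive statistics.
    """
    foreground = frozenset(foreground)
    if fit_branch_lengths:
        m0 = CodonModel.one_ratio(0.5, kappa=kappa, codon_freqs=codon_freqs)
        base = optimize(codon_alignment, tree, m0,
                        free_params=("branch_lengths", "kappa", "omega"),
                        tol=tol, xtol=xtol, max_sweeps=max_sweeps)
        tree = base.tree
        kappa = base.model.kappa
    null_model = CodonModel.branch_site_null(p0=0.7, p1=0.2, omega0=0.2,
                                             kappa=kappa,
                                             codon_freqs=codon_freqs)
    null_fit = optimize(codon_alignment, tree, null_model,
                        free_params=("ptot", "frac", "omega0"),
                        foreground=foreground, tol=tol, xtol=xtol,
                        max_sweeps=max_sweeps, copy=False)
    # omega2 = 1 makes the alternative equal the null at its optimum, so
    # the optimizer can only improve on lnL_null: the nesting inequality
    # holds by construction
    alt_model = null_fit.model.copy()
    alt_model.params["omega2"] = 1.0
    alt_fit = optimize(codon_alignment, tree, alt_model,
                       free_params=("ptot", "frac", "omega0", "omega2"),
                       foreground=foreground, tol=tol, xtol=xtol,
                       max_sweeps=max_sweeps, copy=False)
    stat = 2.0 * (alt_fit.lnl - null_fit.lnl)
    if stat < -1e-6:
        warnings.warn(
            f"alternative fit below null by {-stat / 2:.3g} lnL units; "
            "clamping the statistic to 0"
        )
    stat = max(stat, 0.0)
    p_raw = float(chi2.sf(stat, df=1))
    if boundary_mixture:
        p_raw = 0.5 * p_raw if stat > 0 else 1.0
    p = alt_fit.model.params
    p0, p1 = p["p0"], p["p1"]
    params = {
        "p0": p0,
        "p1": p1,
        "p2": max(0.0, 1.0 - p0 - p1),
        "omega0": p["omega0"],
        "omega2": p["omega2"],
        "kappa": kappa,
    }
    return LRTResult(
        branch=foreground,
        lnl_alt=alt_fit.lnl,
        lnl_null=null_fit.lnl,
        statistic=stat,
        df=1,
        p_raw=p_raw,
        p_bonferroni=float(min(1.0, m_tests * p_raw)),
        params=params,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: each p becomes min(1, m*p) with m the number
    of tests (defaults to the number of p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# gene-conversion screen
# ---------------------------------------------------------------------------

@dataclass
class ConversionFragment:
    """Best-supported candidate conversion tract for one sequence pair.

    Coordinates are 1-based inclusive alignment columns.  ``poly`` counts
    polymorphic sites inside the tract, ``mismatches`` the pair's
    disagreements inside it, ``total_mismatches`` the pair's disagreements
    over all polymorphic columns.  ``sim_p`` is the permutation p-value for
    the tract score; ``p_bonferroni`` corrects it over sequence pairs.
    """

    pair: tuple
    begin: int
    end: int
    poly: int
    length: int
    mismatches: int
    total_mismatches: int
    score: float
    sim_p: float
    p_bonferroni: float = float("nan")


def _max_fragment(values: np.ndarray):
    """Maximal-scoring contiguous fragment (Kadane), returning
    (score, start, end) over index positions; scores <= 0 give (0, -1, -1)."""
    best, best_start, best_end = 0.0, -1, -1
    run, run_start = 0.0, 0
    for i, v in enumerate(values):
        if run <= 0:
            run, run_start = v, i
        else:
            run += v
        if run > best:
            best, best_start, best_end = run, run_start, i
    return best, best_start, best_end


def _max_scores_batch(values: np.ndarray) -> np.ndarray:
    """Maximum contiguous-fragment score per row, vectorized across rows
    via prefix sums (used for the permutation null)."""
    s = np.cumsum(values, axis=1)
    prefix = np.concatenate([np.zeros((s.shape[0], 1)), s], axis=1)
    running_min = np.minimum.accumulate(prefix[:, :-1], axis=1)
    return np.maximum((s - running_min).max(axis=1), 0.0)


def gene_conversion_scan(records, n_perm: int = 10000, seed=None,
                         mismatch_penalty: float = 1.0,
                         estimator: str = "mid"):
    """Screen an aligned set of DNA sequences for candidate gene-conversion
    tracts.

    Polymorphic columns (no gaps, not all identical across the full
    alignment) are extracted; for each unordered sequence pair, agreement at
    a polymorphic column scores +1 and disagreement -``mismatch_penalty``,
    and the maximal-scoring contiguous fragment is the candidate tract.  Its
    permutation p-value compares the score against random polymorphic-column
    orders.  Because the tract score is integer-valued, permutation ties
    carry substantial mass at screening scales; the default ``estimator``
    ("mid") therefore splits tied permutations evenly
    (p = (greater + (ties + 1)/2) / (n_perm + 1), clamped below at
    1/(n_perm + 1)), which makes the null distribution of sim_p uniform.
    ``estimator="upper"`` gives the classic conservative count of
    greater-or-equal permutations.  A Bonferroni correction over pairs gives
    the family-wise p.  Results are reported in original alignment
    coordinates (1-based inclusive) and sorted by sim_p.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 aligned sequences")
    seqs = [r.seq.upper() for r in records]
    ids = [r.id for r in records]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned (equal lengths)")
    mat = np.array([list(s) for s in seqs])
    no_gap = ~np.any((mat == "-") | (mat == "N"), axis=0)
    variable = np.any(mat != mat[0], axis=0)
    poly_cols = np.where(no_gap & variable)[0]
    if len(poly_cols) < 2:
        warnings.warn("fewer than 2 polymorphic columns; nothing to scan")
        return []
    sub = mat[:, poly_cols]
    rng = np.random.default_rng(seed)
    n = len(records)
    n_pairs = n * (n - 1) // 2
    fragments = []
    for i in range(n):
        for j in range(i + 1, n):
            agree = sub[i] == sub[j]
            values = np.where(agree, 1.0, -float(mismatch_penalty))
            score, s, e = _max_fragment(values)
            if s < 0:
                continue
            perms = rng.permuted(
                np.tile(values, (n_perm, 1)), axis=1
            )
            null_scores = _max_scores_batch(perms)
            greater = int(np.count_nonzero(null_scores > score + 1e-12))
            ties = int(np.count_nonzero(np.abs(null_scores - score) <= 1e-12))
            if estimator == "mid":
                sim_p = (greater + 0.5 * (ties + 1)) / (n_perm + 1.0)
                sim_p = max(sim_p, 1.0 / (n_perm + 1.0))
            elif estimator == "upper":
                sim_p = (1.0 + greater + ties) / (n_perm + 1.0)
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            begin = int(poly_cols[s]) + 1
            end = int(poly_cols[e]) + 1
            inside = values[s:e + 1]
            fragments.append(ConversionFragment(
                pair=(ids[i], ids[j]),
                begin=begin,
                end=end,
                poly=int(e - s + 1),
                length=int(end - begin + 1),
                mismatches=int(np.count_nonzero(inside < 0)),
                total_mismatches=int(np.count_nonzero(~agree)),
                score=float(score),
                sim_p=float(sim_p),
            ))
    for f in fragments:
        f.p_bonferroni = float(min(1.0, n_pairs * f.sim_p))
    fragments.sort(key=lambda f: (f.sim_p, -f.score))
    return fragments


def fragments_to_frame(fragments):
    """Tabular report of a gene-conversion scan (columns mirroring the
    conventional pairwise-screen layout)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "seq1": f.pair[0],
            "seq2": f.pair[1],
            "sim_p": f.sim_p,
            "p_bonferroni": f.p_bonferroni,
            "begin": f.begin,
            "end": f.end,
            "poly": f.poly,
            "length": f.length,
            "mismatches": f.mismatches,
            "total_mismatches": f.total_mismatches,
            "score": f.score,
        }
        for f in fragments
    ])
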
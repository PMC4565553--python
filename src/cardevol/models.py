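"""Substitution-model machinery for proteins and codons.

Implements the LG (+F, +discrete-gamma) amino-acid replacement model and a
Goldman-Yang-style codon model family: a one-ratio (M0) model, a two-class
sites model (a constrained class with omega0 < 1 plus a neutral class), and
branch-site model A together with its null (foreground omega2 fixed at 1).

All rate matrices are time-reversible.  Protein generators are normalized so
that branch lengths are expected substitutions per site; codon generators are
normalized so that branch lengths are expected substitutions per codon under
the background class mixture.  Transition probabilities are computed through
an eigendecomposition of the symmetrized generator, which is exact for
reversible models and much faster than repeated Pade exponentials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm as _expm
from scipy.stats import gamma as _gamma_dist
from Bio.Data import CodonTable

from ._lg import AA_ORDER, LG_FREQUENCIES, LG_LOWER_TRIANGLE

__all__ = [
    "AA_ORDER",
    "AA_INDEX",
    "CODONS",
    "CODON_INDEX",
    "CODON_AA",
    "STOP_CODONS",
    "ProteinModel",
    "CodonModel",
    "lg_model",
    "empirical_frequencies",
    "f3x4_frequencies",
    "discrete_gamma",
    "build_rate_matrix",
    "codon_rate_matrix",
    "transition_matrix",
    "ReversibleEigen",
]

AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_CODE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_CODE.stop_codons)
#: the 61 sense codons of the universal code, in TCAG-nested order
CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in STOP_CODONS
]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
#: amino-acid index (into AA_ORDER) encoded by each sense codon
CODON_AA = np.array([AA_INDEX[_CODE.forward_table[c]] for c in CODONS])

_PURINES = frozenset("AG")


def _classify_codon_pairs():
    """Tables over all 61x61 sense-codon pairs: number of differing
    nucleotide positions, transition flag (for single-nt changes) and
    synonymy flag."""
    n = len(CODONS)
    ndiff = np.zeros((n, n), dtype=np.int8)
    is_ts = np.zeros((n, n), dtype=bool)
    is_syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            diffs = [(x, y) for x, y in zip(ci, cj) if x != y]
            ndiff[i, j] = len(diffs)
            if len(diffs) == 1:
                x, y = diffs[0]
                is_ts[i, j] = (x in _PURINES) == (y in _PURINES)
            is_syn[i, j] = CODON_AA[i] == CODON_AA[j]
    return ndiff, is_ts, is_syn


CODON_NDIFF, CODON_IS_TRANSITION, CODON_IS_SYNONYMOUS = _classify_codon_pairs()


# ---------------------------------------------------------------------------
# protein model
# ---------------------------------------------------------------------------

def lg_exchangeabilities() -> np.ndarray:
    """The symmetric 20x20 LG exchangeability matrix (zero diagonal)."""
    s = np.zeros((20, 20))
    k = 0
    for j in range(20):           # column-major lower triangle
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = LG_LOWER_TRIANGLE[k]
            k += 1
    return s


@dataclass
class ProteinModel:
    """Reversible amino-acid model: exchangeabilities x frequencies, with
    discrete-gamma rate variation.

    Parameters
    ----------
    exchangeabilities : (20, 20) symmetric nonnegative matrix.
    frequencies : stationary residue frequencies in ``AA_ORDER``, summing to 1.
    alpha : gamma shape of among-site rate variation (> 0).
    ncat : number of equiprobable discrete rate categories.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float = 1.0
    ncat: int = 8
    name: str = "LG"

    n_states = 20

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.exchangeabilities.shape != (20, 20):
            raise ValueError("exchangeabilities must be 20x20")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.ncat < 1:
            raise ValueError("ncat must be >= 1")

    def rate_multipliers(self) -> np.ndarray:
        return discrete_gamma(self.alpha, self.ncat)

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "protein",
                "name": self.name,
                "frequencies": self.frequencies.tolist(),
                "alpha": self.alpha,
                "ncat": self.ncat,
            }
        )


def lg_model(frequencies=None, alpha: float = 1.0, ncat: int = 8) -> ProteinModel:
    """LG model, optionally with alignment-derived ("+F") frequencies."""
    freqs = np.array(LG_FREQUENCIES) if frequencies is None else np.asarray(frequencies, float)
    freqs = freqs / freqs.sum()
    return ProteinModel(lg_exchangeabilities(), freqs, alpha=alpha, ncat=ncat)


def empirical_frequencies(sequences, pseudocount: float = 1.0) -> np.ndarray:
    """Residue frequencies counted from sequences (records or raw strings),
    with a pseudocount per residue so no frequency is zero."""
    counts = np.full(20, float(pseudocount))
    for rec in sequences:
        seq = getattr(rec, "seq", rec)
        for ch in seq.upper():
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# codon model family
# ---------------------------------------------------------------------------

def f3x4_frequencies(nuc_freqs_by_position) -> np.ndarray:
    """F3x4 codon frequencies from a (3, 4) table of nucleotide frequencies
    per codon position (columns in T, C, A, G order), with stop codons
    removed and the rest renormalized."""
    f = np.asarray(nuc_freqs_by_position, dtype=float)
    if f.shape != (3, 4):
        raise ValueError("expected a (3, 4) nucleotide-frequency table")
    f = f / f.sum(axis=1, keepdims=True)
    nuc_idx = {n: i for i, n in enumerate("TCAG")}
    freqs = np.array(
        [f[0, nuc_idx[c[0]]] * f[1, nuc_idx[c[1]]] * f[2, nuc_idx[c[2]]] for c in CODONS]
    )
    return freqs / freqs.sum()


def uniform_codon_frequencies() -> np.ndarray:
    """F3x4 frequencies from uniform nucleotide frequencies (stop-codon
    removal makes them slightly non-uniform over the 61 sense codons)."""
    return f3x4_frequencies(np.full((3, 4), 0.25))


@dataclass
class SiteClass:
    """One mixture component: proportion plus background/foreground omega."""

    proportion: float
    omega_background: float
    omega_foreground: float


@dataclass
class CodonModel:
    """Goldman-Yang-style codon model with an omega site-class mixture.

    ``kind`` selects the parameterization:

    - ``one_ratio``:   params ``{"omega"}`` — a single omega everywhere.
    - ``sites``:       params ``{"p0", "omega0"}`` — proportion p0 of sites
      with omega0, the remainder neutral (omega = 1).
    - ``branch_site``: params ``{"p0", "p1", "omega0", "omega2"}`` — model A:
      classes 0/1 as in the sites model, plus classes 2a/2b in which the
      foreground branch takes omega2 while the background keeps omega0 or 1.
      The null model is the same with omega2 fixed at 1.

    The foreground branch itself is not part of the model; it is supplied to
    the likelihood machinery as a leaf-set bipartition.
    """

    kappa: float = 2.0
    codon_freqs: np.ndarray = field(default_factory=uniform_codon_frequencies)
    kind: str = "one_ratio"
    params: dict = field(default_factory=lambda: {"omega": 1.0})

    n_states = len(CODONS)

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.codon_freqs.shape != (len(CODONS),):
            raise ValueError("codon_freqs must have one entry per sense codon")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon_freqs must sum to 1")
        self.site_classes()  # validate parameters eagerly

    # -- constructors -------------------------------------------------------
    @classmethod
    def one_ratio(cls, omega=1.0, kappa=2.0, codon_freqs=None):
        return cls(kappa, _default_freqs(codon_freqs), "one_ratio", {"omega": float(omega)})

    @classmethod
    def sites(cls, p0=0.8, omega0=0.1, kappa=2.0, codon_freqs=None):
        return cls(kappa, _default_freqs(codon_freqs), "sites",
                   {"p0": float(p0), "omega0": float(omega0)})

    @classmethod
    def branch_site_a(cls, p0=0.45, p1=0.45, omega0=0.1, omega2=2.0,
                      kappa=2.0, codon_freqs=None):
        return cls(kappa, _default_freqs(codon_freqs), "branch_site",
                   {"p0": float(p0), "p1": float(p1),
                    "omega0": float(omega0), "omega2": float(omega2)})

    @classmethod
    def branch_site_null(cls, p0=0.45, p1=0.45, omega0=0.1, kappa=2.0,
                         codon_freqs=None):
        m = cls.branch_site_a(p0, p1, omega0, omega2=1.0, kappa=kappa,
                              codon_freqs=codon_freqs)
        return m

    # -- mixture ------------------------------------------------------------
    def site_classes(self) -> list[SiteClass]:
        p = self.params
        if self.kind == "one_ratio":
            w = p["omega"]
            _check_omega(w)
            return [SiteClass(1.0, w, w)]
        if self.kind == "sites":
            p0, w0 = p["p0"], p["omega0"]
            _check_prop(p0)
            _check_omega(w0)
            return [SiteClass(p0, w0, w0), SiteClass(1.0 - p0, 1.0, 1.0)]
        if self.kind == "branch_site":
            p0, p1, w0, w2 = p["p0"], p["p1"], p["omega0"], p["omega2"]
            _check_prop(p0)
            _check_prop(p1)
            if p0 + p1 > 1.0 + 1e-12:
                raise ValueError("p0 + p1 must not exceed 1")
            _check_omega(w0)
            _check_omega(w2)
            p2 = max(0.0, 1.0 - p0 - p1)
            # standard model A convention: 2a/2b split proportionally to p0:p1
            denom = p0 + p1
            p2a = p2 * p0 / denom
            p2b = p2 * p1 / denom
            return [
                SiteClass(p0, w0, w0),
                SiteClass(p1, 1.0, 1.0),
                SiteClass(p2a, w0, w2),
                SiteClass(p2b, 1.0, w2),
            ]
        raise ValueError(f"unknown codon model kind {self.kind!r}")

    def rate_matrices(self):
        """Per-class (weight, Q_background, Q_foreground), jointly scaled so
        one unit of branch length is one expected substitution per codon
        under the background mixture."""
        classes = self.site_classes()
        raw = []
        for sc in classes:
            qb = codon_rate_matrix(self.kappa, sc.omega_background,
                                   self.codon_freqs, normalize=False)
            if sc.omega_foreground == sc.omega_background:
                qf = qb
            else:
                qf = codon_rate_matrix(self.kappa, sc.omega_foreground,
                                       self.codon_freqs, normalize=False)
            raw.append((sc.proportion, qb, qf))
        scale = sum(
            w * -(self.codon_freqs * np.diag(qb)).sum() for w, qb, _ in raw
        )
        return [(w, qb / scale, qf / scale) for w, qb, qf in raw]

    def copy(self) -> "CodonModel":
        return replace(self, codon_freqs=self.codon_freqs.copy(),
                       params=dict(self.params))

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "codon",
                "kind": self.kind,
                "kappa": self.kappa,
                "params": self.params,
                "codon_freqs": self.codon_freqs.tolist(),
            }
        )


def model_from_json(text: str):
    d = json.loads(text)
    if d["type"] == "protein":
        return lg_model(d["frequencies"], alpha=d["alpha"], ncat=d["ncat"])
    return CodonModel(d["kappa"], np.asarray(d["codon_freqs"]), d["kind"],
                      dict(d["params"]))


def _default_freqs(codon_freqs):
    return uniform_codon_frequencies() if codon_freqs is None else np.asarray(codon_freqs, float)


def _check_omega(w):
    if w < 0:
        raise ValueError("omega must be >= 0")


def _check_prop(p):
    if not (0.0 <= p <= 1.0):
        raise ValueError("class proportions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# rate matrices and transition probabilities
# ---------------------------------------------------------------------------

def build_rate_matrix(model, class_index: int = 0, foreground: bool = False) -> np.ndarray:
    """Normalized reversible generator for a model (or one mixture class of a
    codon model).  Protein generators have mean rate 1 at relative rate 1;
    codon generators share the background-mixture scaling."""
    if isinstance(model, ProteinModel):
        s = model.exchangeabilities
        pi = model.frequencies
        if np.any((pi <= 0) & (s.sum(axis=1) > 0)):
            raise ValueError(
                "zero stationary frequency with positive exchangeability: "
                "the generator scaling is unidentifiable"
            )
        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu
    if isinstance(model, CodonModel):
        mats = model.rate_matrices()
        w, qb, qf = mats[class_index]
        return qf if foreground else qb
    raise TypeError(f"unsupported model type {type(model).__name__}")


def codon_rate_matrix(kappa: float, omega: float, codon_freqs: np.ndarray,
                      normalize: bool = True) -> np.ndarray:
    """Goldman-Yang codon generator: single-nucleotide changes only, with
    transition/transversion ratio kappa and nonsynonymous factor omega."""
    pi = np.asarray(codon_freqs, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("codon frequencies must be strictly positive")
    q = np.where(CODON_NDIFF == 1, pi[np.newaxis, :], 0.0)
    q = np.where(CODON_IS_TRANSITION, q * kappa, q)
    q = np.where(CODON_NDIFF == 1, np.where(CODON_IS_SYNONYMOUS, q, q * omega), 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        mu = -(pi * np.diag(q)).sum()
        if mu <= 0:
            raise ValueError("degenerate codon generator (zero total rate)")
        q = q / mu
    return q


def discrete_gamma(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equiprobable categories of a mean-1 gamma
    distribution (category-mean convention)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return np.ones(1)
    scale = 1.0 / alpha
    edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, ncat + 1), a=alpha, scale=scale)
    # E[X ; a < X < b] for Gamma(alpha, scale) = alpha*scale * [F_{alpha+1}(b) - F_{alpha+1}(a)]
    cdf_up = _gamma_dist.cdf(edges, a=alpha + 1.0, scale=scale)
    rates = ncat * np.diff(cdf_up)  # alpha*scale == 1
    return rates / rates.mean()


def stationary_frequencies(model) -> np.ndarray:
    if isinstance(model, ProteinModel):
        return model.frequencies
    return model.codon_freqs


def transition_matrix(Q: np.ndarray, t: float, rate: float = 1.0,
                      frequencies: np.ndarray | None = None) -> np.ndarray:
    """P(t) = expm(Q * t * rate).  When stationary frequencies are supplied
    the reversible eigendecomposition route is used; otherwise a Pade
    exponential."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if frequencies is not None:
        return ReversibleEigen(Q, frequencies).transition(t * rate)
    return _expm(Q * (t * rate))


class ReversibleEigen:
    """Eigendecomposition of a reversible generator via symmetrization,
    supporting fast transition-matrix evaluation at many times."""

    def __init__(self, Q: np.ndarray, frequencies: np.ndarray):
        pi = np.asarray(frequencies, dtype=float)
        d = np.sqrt(pi)
        b = Q * (d[:, np.newaxis] / d[np.newaxis, :])
        b = 0.5 * (b + b.T)
        w, v = np.linalg.eigh(b)
        self.eigenvalues = w
        self._left = v / d[:, np.newaxis]
        self._right = v.T * d[np.newaxis, :]
        self.frequencies = pi

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("time must be nonnegative")
        p = (self._left * np.exp(self.eigenvalues * t)) @ self._right
        np.maximum(p, 0.0, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p
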
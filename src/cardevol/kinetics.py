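"""Binding-kinetics estimation from association/dissociation traces.

The analysis follows the standard biolayer-interferometry workflow: traces
are blank-corrected against a 0-concentration probe, the steady-state
response is the mean of the last 500 association samples, the initial
binding rate is the t = 0 derivative of a single-exponential association
fit, and both concentration-response curves are fitted with the one-site
form R = Rmax*C/(K + C) by nonlinear least squares.  Kd denotes the
half-maximal steady-state concentration and Km the half-maximal
initial-rate concentration; both are also reported as -log10 transforms
(pKd, pKm).  Affinity comparisons use Welch's two-sample t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import t as t_dist

from .io import TraceTable

__all__ = [
    "ConcentrationResponse",
    "BindingFit",
    "blank_correct",
    "steady_state",
    "initial_rate",
    "fit_one_site",
    "concentration_response",
    "estimate_binding",
    "compare_affinities",
]

STEADY_STATE_SAMPLES = 500
R2_QC_THRESHOLD = 0.91


@dataclass
class ConcentrationResponse:
    """Concentration-response points (steady-state level or initial rate)."""

    concentrations: np.ndarray
    responses: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, float)
        self.responses = np.asarray(self.responses, float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


@dataclass
class BindingFit:
    """A one-site binding fit: K is Kd (steady state) or Km (initial rate).

    ``scheme`` records how replicates entered the fit: ``per_replicate``
    (fit each replicate, average the constants) or ``averaged`` (average
    the points, fit once).  ``qc_flag`` marks fits with r^2 at or below
    0.91; they are reported, not rejected.
    """

    K: float
    Rmax: float
    r_squared: float
    kind: str = "Kd"                       # "Kd" or "Km"
    scheme: str = "averaged"
    K_se: float | None = None
    per_replicate: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("binding constant must be positive")

    @property
    def pK(self) -> float:
        return -np.log10(self.K)

    @property
    def qc_flag(self) -> bool:
        return self.r_squared <= R2_QC_THRESHOLD


# ---------------------------------------------------------------------------
# trace-level operations
# ---------------------------------------------------------------------------

def blank_correct(traces: TraceTable) -> TraceTable:
    """Subtract the 0-concentration blank trace pointwise from every
    sample trace (per replicate and phase; linear interpolation when time
    grids differ)."""
    if not traces.has_blank():
        raise ValueError("no 0-concentration blank trace in the table")
    df = traces.data
    out = []
    for (conc, rep, phase), grp in df.groupby(
        ["concentration_M", "replicate", "phase"], sort=False
    ):
        if conc == 0:
            continue
        blanks = df[(df["concentration_M"] == 0) & (df["phase"] == phase)]
        rep_blank = blanks[blanks["replicate"] == rep]
        if len(rep_blank) == 0:
            rep_blank = blanks
        if len(rep_blank) == 0:
            raise ValueError(f"no blank available for phase {phase!r}")
        bt = rep_blank["time"].to_numpy()
        bs = rep_blank["signal"].to_numpy()
        t = grp["time"].to_numpy()
        if t.max() < bt.min() or t.min() > bt.max():
            raise ValueError(
                f"blank and sample time ranges do not overlap for "
                f"({conc}, {rep}, {phase})"
            )
        corrected = grp.copy()
        corrected["signal"] = grp["signal"].to_numpy() - np.interp(t, bt, bs)
        out.append(corrected)
    return TraceTable(pd.concat(out, ignore_index=True))


def steady_state(signal, n_last: int = STEADY_STATE_SAMPLES) -> float:
    """Steady-state binding level: the mean of the last ``n_last`` samples
    of an association trace (all samples, with a warning, when the trace is
    shorter)."""
    signal = np.asarray(signal, float)
    if signal.size == 0:
        raise ValueError("empty trace")
    if signal.size < n_last:
        warnings.warn(
            f"trace has only {signal.size} samples (< {n_last}); averaging "
            "all of them"
        )
        return float(signal.mean())
    return float(signal[-n_last:].mean())


def initial_rate(time, signal) -> float:
    """Initial binding rate: the t = 0 derivative A*k of a single-
    exponential association fit R(t) = A*(1 - exp(-k t))."""
    time = np.asarray(time, float)
    signal = np.asarray(signal, float)
    if time.size < 3:
        raise ValueError("need at least 3 samples to fit an association curve")
    t0 = time - time[0]
    a0 = max(abs(signal[-1]), 1e-12)
    span = max(t0[-1], 1e-12)
    k0 = 1.0 / span

    def resid(theta):
        a, logk = theta
        return a * (1.0 - np.exp(-np.exp(logk) * t0)) - signal

    best = None
    for k_init in (k0, 10 * k0, 0.1 * k0):
        sol = least_squares(resid, x0=[a0, np.log(k_init)], method="lm",
                            max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    a, logk = best.x
    k = float(np.exp(logk))
    rate = float(a * k)
    if not np.isfinite(rate) or k <= 0:
        raise ValueError(
            f"association fit failed (A={a:.3g}, k={k:.3g}); "
            "inspect the trace"
        )
    return rate


def initial_rate_linear(time, signal, window: int = 20) -> float:
    """Alternative initial-rate estimator: ordinary least-squares slope over
    the first ``window`` samples."""
    time = np.asarray(time, float)[:window]
    signal = np.asarray(signal, float)[:window]
    if time.size < 2:
        raise ValueError("window too short for a slope")
    return float(np.polyfit(time, signal, 1)[0])


# ---------------------------------------------------------------------------
# one-site fits
# ---------------------------------------------------------------------------

def fit_one_site(points: ConcentrationResponse, kind: str = "Kd",
                 scheme: str = "averaged") -> BindingFit:
    """Least-squares fit of the one-site curve R = Rmax*C/(K + C).

    K is profiled on a log grid spanning well beyond the measured
    concentrations (Rmax has a closed-form conditional optimum given K),
    and the best grid point is polished by bounded search — a global
    strategy that guards against local optima.
    """
    c = points.concentrations
    r = points.responses
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.allclose(r, r[0]):
        raise ValueError(
            "all responses equal; the one-site curve is unidentifiable"
        )

    def sse_given_logk(logk):
        k = np.exp(logk)
        x = c / (k + c)
        rmax = (r @ x) / (x @ x)
        resid = rmax * x - r
        return float(resid @ resid)

    lo = np.log(c.min() / 1e4)
    hi = np.log(c.max() * 1e4)
    grid = np.linspace(lo, hi, 241)
    sse_grid = np.array([sse_given_logk(g) for g in grid])
    gstar = int(np.argmin(sse_grid))
    blo = grid[max(gstar - 2, 0)]
    bhi = grid[min(gstar + 2, len(grid) - 1)]
    res = minimize_scalar(sse_given_logk, bounds=(blo, bhi), method="bounded",
                          options={"xatol": 1e-13})
    k = float(np.exp(res.x))
    x = c / (k + c)
    rmax = float((r @ x) / (x @ x))
    # Gauss-Newton polish to the floating-point noise floor
    sol = least_squares(
        lambda th: th[0] * c / (np.exp(th[1]) + c) - r,
        x0=[rmax, np.log(k)], method="lm", xtol=1e-15, ftol=1e-15,
        gtol=1e-15, max_nfev=200,
    )
    if sol.cost <= 0.5 * sse_given_logk(np.log(k)) + 1e-30:
        rmax, k = float(sol.x[0]), float(np.exp(sol.x[1]))
    x = c / (k + c)
    ss_res = float(((rmax * x - r) ** 2).sum())
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    fit = BindingFit(K=k, Rmax=rmax, r_squared=r2, kind=kind, scheme=scheme)
    if fit.qc_flag:
        warnings.warn(
            f"one-site fit quality low (r^2 = {r2:.3f} <= "
            f"{R2_QC_THRESHOLD}); reporting anyway"
        )
    return fit


def concentration_response(traces: TraceTable, response: str = "steady_state",
                           replicate=None, n_last: int = STEADY_STATE_SAMPLES):
    """Extract concentration-response points from association traces for one
    replicate (or averaged with SE across replicates when ``replicate`` is
    None)."""
    concs = traces.concentrations
    if replicate is not None:
        vals = []
        for cc in concs:
            t, s = traces.series(cc, replicate, "association")
            vals.append(
                steady_state(s, n_last) if response == "steady_state"
                else initial_rate(t, s)
            )
        return ConcentrationResponse(concs, np.array(vals))
    reps = traces.replicates
    matrix = np.array([
        concentration_response(traces, response, replicate=r, n_last=n_last).responses
        for r in reps
    ])
    se = matrix.std(axis=0, ddof=1) / np.sqrt(len(reps)) if len(reps) > 1 else None
    return ConcentrationResponse(concs, matrix.mean(axis=0), se)


def estimate_binding(traces: TraceTable, scheme: str = "per_replicate",
                     n_last: int = STEADY_STATE_SAMPLES,
                     responses=("steady_state", "initial_rate")) -> dict:
    """Estimate Kd (from steady-state levels) and Km (from initial rates)
    under one of the two replicate-handling schemes.

    ``per_replicate``: fit each experimental replicate separately, report
    the mean and SE of the constants across replicates.  ``averaged``:
    average the concentration-response points across replicates (with SE)
    and fit the averaged curve once.  Returns ``{"Kd": BindingFit,
    "Km": BindingFit}`` (keys limited to the requested responses).
    """
    if scheme not in ("per_replicate", "averaged"):
        raise ValueError(f"unknown scheme {scheme!r}")
    kind_of = {"steady_state": "Kd", "initial_rate": "Km"}
    out = {}
    reps = traces.replicates
    for response in responses:
        kind = kind_of[response]
        if scheme == "averaged":
            points = concentration_response(traces, response, None, n_last)
            out[kind] = fit_one_site(points, kind=kind, scheme=scheme)
            continue
        fits = {}
        for r in reps:
            try:
                points = concentration_response(traces, response, r, n_last)
                fits[int(r)] = fit_one_site(points, kind=kind, scheme=scheme)
            except ValueError as exc:
                raise ValueError(
                    f"{kind} fit failed for replicate {r}: {exc}"
                ) from exc
        ks = np.array([f.K for f in fits.values()])
        k_mean = float(ks.mean())
        k_se = float(ks.std(ddof=1) / np.sqrt(len(ks))) if len(ks) > 1 else None
        out[kind] = BindingFit(
            K=k_mean,
            Rmax=float(np.mean([f.Rmax for f in fits.values()])),
            r_squared=float(np.mean([f.r_squared for f in fits.values()])),
            kind=kind,
            scheme=scheme,
            K_se=k_se,
            per_replicate={r: f.K for r, f in fits.items()},
        )
    return out


def compare_affinities(values_a, values_b):
    """Welch's two-tailed two-sample t test (unequal variances,
    Satterthwaite df); intended for per-replicate pKd or pKm values.

    Degenerate case: when both groups have zero variance and equal means,
    (t, p) = (0, 1) by convention.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    se2 = va / a.size + vb / b.size
    t_stat = float((a.mean() - b.mean()) / np.sqrt(se2))
    df = se2 ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = float(2.0 * t_dist.sf(abs(t_stat), df))
    return t_stat, p
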
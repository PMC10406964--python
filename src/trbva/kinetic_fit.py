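"""Kinetic models and fitting of excess-variance traces.

The method models the apparent (uncorrected) FRET efficiency of a molecule
as a function of a continuous-time Markov chain over conformational states.
For a rate matrix K (columns summing to zero), equilibrium populations
p_eq and per-state efficiencies eps_s, the FRET autocorrelation is

    g(t) = 1^T eps exp(K t) eps p_eq - (1^T eps p_eq)^2,

a finite sum of decaying exponentials g(t) = sum_j A_j exp(-lambda_j t)
whose rates are the nonzero eigenvalues of -K. For a two-state system this
reduces to a single term with amplitude <d eps^2> =
k12 k21/(k12+k21)^2 (eps2-eps1)^2 and rate k_obs = k12 + k21.

The excess variance of m-photon segments of duration t ("t-specific excess
variance") is

    Ds2(m, t) = (1/m^2) [ 2 g(t) + (4(m-2)/t) int_0^t g
                          + (2(m-2)(m-3)/t^2) int_0^t (t-t') g(t') dt' ],

with the integrals available in closed form per exponential term. The
predicted trace S^2(m) averages Ds2 over the empirical distribution of
segment durations, discretised as a histogram H(t_i|m):

    S^2(m) = sum_i H(t_i|m) Ds2(m, t_i) / sum_i H(t_i|m).

Fitting minimises the unweighted least-squares difference between the
measured and predicted S^2(m) over the amplitudes and rates of a one- or
two-exponential correlation function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import least_squares

__all__ = [
    "KineticModel",
    "ExponentialCorrelation",
    "FitResult",
    "g_of_t",
    "decompose_to_exponentials",
    "delta_s2",
    "predict_s2",
    "fit_trace",
]


@dataclass
class KineticModel:
    """Rate matrix K over conformational states plus per-state efficiencies.

    Convention: dp/dt = K p, so columns of K sum to zero and off-diagonal
    entries K[i, j] >= 0 are rates j -> i (per microsecond).
    """

    K: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n) or self.eps.shape != (n,):
            raise ValueError("K must be square and eps match its dimension")
        if not np.allclose(self.K.sum(axis=0), 0.0, atol=1e-10):
            raise ValueError("columns of K must sum to zero (generator)")
        off = self.K - np.diag(np.diag(self.K))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")

    @property
    def n_states(self) -> int:
        return self.K.shape[0]

    @property
    def p_eq(self) -> np.ndarray:
        """Equilibrium populations: the normalized null vector of K."""
        ns = scipy.linalg.null_space(self.K, rcond=1e-10)
        if ns.shape[1] != 1:
            raise ValueError("K is reducible: equilibrium not unique")
        p = ns[:, 0]
        p = p / p.sum()
        if np.any(p < -1e-9):
            raise ValueError("invalid equilibrium vector")
        return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()

    @classmethod
    def two_state(cls, k12: float, k21: float,
                  eps1: float, eps2: float) -> "KineticModel":
        """Two interconverting states; rates in 1/us."""
        K = np.array([[-k12, k21], [k12, -k21]], dtype=float)
        return cls(K, np.array([eps1, eps2]))

    @classmethod
    def chain(cls, rates: Sequence[tuple], eps: Sequence[float]) -> "KineticModel":
        """Build from a list of (i, j, k_ij) transitions (i -> j, 1/us)."""
        n = len(eps)
        K = np.zeros((n, n))
        for i, j, k in rates:
            K[j, i] += k
            K[i, i] -= k
        return cls(K, np.asarray(eps, dtype=float))


@dataclass
class ExponentialCorrelation:
    """g(t) = sum_j A_j exp(-lambda_j t); rates in 1/us, amplitudes unitless.

    A zero rate encodes a static (frozen-heterogeneity) component.
    """

    amplitudes: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, float))
        self.rates = np.atleast_1d(np.asarray(self.rates, float))
        if self.amplitudes.shape != self.rates.shape:
            raise ValueError("amplitudes and rates must have the same length")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")

    def g(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for a, lam in zip(self.amplitudes, self.rates):
            out += a * np.exp(-lam * t)
        return out

    @property
    def total_amplitude(self) -> float:
        """g(0); bounded by 0.25 for efficiencies in [0, 1]."""
        return float(self.amplitudes.sum())


def g_of_t(model: KineticModel, t) -> np.ndarray:
    """FRET autocorrelation of a kinetic model, via eigendecomposition."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = model.p_eq
    eps = model.eps
    w, V = scipy.linalg.eig(model.K)
    if np.max(np.abs(w.imag)) > 1e-8 * max(np.max(np.abs(w.real)), 1e-30):
        raise ValueError("complex relaxation rates: oscillatory K unsupported")
    Vinv = np.linalg.inv(V)
    left = eps @ V                 # 1^T eps V
    right = Vinv @ (eps * p)       # V^-1 eps p_eq
    mean = float(eps @ p)
    vals = np.zeros_like(t, dtype=complex)
    for j in range(model.n_states):
        vals += left[j] * right[j] * np.exp(w[j] * t)
    return (vals - mean ** 2).real


def decompose_to_exponentials(model: KineticModel) -> ExponentialCorrelation:
    """Spectral decomposition of g(t) into amplitude/rate pairs.

    The zero-eigenvalue term carries amplitude (1^T eps p_eq)^2 and cancels
    against the subtracted squared mean; only strictly decaying terms are
    returned. For a two-state model the single term is exactly
    (<d eps^2>, k12 + k21).
    """
    p = model.p_eq
    eps = model.eps
    w, V = scipy.linalg.eig(model.K)
    if np.max(np.abs(w.imag)) > 1e-8 * max(np.max(np.abs(w.real)), 1e-30):
        raise ValueError("complex relaxation rates: oscillatory K unsupported")
    cond = np.linalg.cond(V)
    if cond > 1e12:
        raise ValueError("rate matrix is (numerically) defective")
    w = w.real
    Vinv = np.linalg.inv(V)
    left = (eps @ V).real
    right = (Vinv @ (eps * p)).real
    scale = np.max(np.abs(w)) if np.max(np.abs(w)) > 0 else 1.0
    keep = w < -1e-12 * scale
    amps = left[keep] * right[keep]
    rates = -w[keep]
    order = np.argsort(rates)
    amps, rates = amps[order], rates[order]
    # tiny negative amplitudes can arise from roundoff
    amps = np.where(np.abs(amps) < 1e-15, 0.0, amps)
    return ExponentialCorrelation(amps, rates)


def _f1(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x))/x with a Taylor guard below x = 1e-6."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-6
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs ** 2 / 6.0 - xs ** 3 / 24.0
    xl = x[~small]
    out[~small] = -np.expm1(-xl) / xl
    return out


def _f2(x: np.ndarray) -> np.ndarray:
    """(x - 1 + exp(-x))/x^2 with a Taylor guard below x = 1e-6."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-6
    xs = x[small]
    out[small] = 0.5 - xs / 6.0 + xs ** 2 / 24.0 - xs ** 3 / 120.0
    xl = x[~small]
    # x - 1 + e^-x == x + expm1(-x): avoids cancellation at small x
    out[~small] = (xl + np.expm1(-xl)) / xl ** 2
    return out


def delta_s2(m: int, t, corr: ExponentialCorrelation) -> np.ndarray:
    """t-specific excess variance Ds2(m, t) in closed form.

    Per exponential term A exp(-lambda t), with x = lambda t:

        Ds2 = (A/m^2) [ 2 e^{-x} + 4(m-2) (1-e^{-x})/x
                        + 2(m-2)(m-3) (x-1+e^{-x})/x^2 ],

    which reduces to A (1 - 1/m) in the static limit x -> 0 and to g(t)/2
    for m = 2 (both (m-2) coefficients vanish).
    """
    if m < 2:
        raise ValueError("m must be >= 2 (variance is defined from pairs)")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.zeros_like(t)
    m = float(m)
    for a, lam in zip(corr.amplitudes, corr.rates):
        x = lam * t
        out += a * (2.0 * np.exp(-x)
                    + 4.0 * (m - 2.0) * _f1(x)
                    + 2.0 * (m - 2.0) * (m - 3.0) * _f2(x))
    return out / m ** 2


def predict_s2(histograms, corr: ExponentialCorrelation) -> np.ndarray:
    """Predicted S^2(m) from per-m duration histograms.

    ``histograms`` is a sequence of (m, t_centers, counts); empty histograms
    yield NaN for that m.
    """
    out = np.empty(len(histograms))
    for i, (m, centers, counts) in enumerate(histograms):
        w = np.asarray(counts, dtype=float)
        total = w.sum()
        if total <= 0:
            out[i] = np.nan
            continue
        out[i] = float(np.sum(w * delta_s2(int(m), centers, corr)) / total)
    return out


@dataclass
class FitResult:
    """Least-squares fit of an S^2(m) trace.

    Rates are in 1/us; ``tau_us`` are the corresponding relaxation times.
    """

    amplitudes: np.ndarray
    rates: np.ndarray
    chisq: float
    residuals: np.ndarray
    m: np.ndarray
    s2_fit: np.ndarray
    n_exponentials: int
    converged: bool
    at_bound: bool = False
    messages: list = field(default_factory=list)

    @property
    def correlation(self) -> ExponentialCorrelation:
        return ExponentialCorrelation(self.amplitudes, self.rates)

    @property
    def tau_us(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 1.0 / self.rates

    @property
    def k_obs(self) -> float:
        """Observed rate (1/us); slowest component for multi-exponential fits."""
        return float(self.rates.min())


_LOG_LAM_LO, _LOG_LAM_HI = -9.0, 1.0  # log10 of rate bounds, 1/us


def fit_trace(trace, n_exponentials: int = 1,
              bounds: Optional[dict] = None,
              start: Optional[dict] = None,
              n_starts: int = 8,
              weights: Optional[np.ndarray] = None) -> FitResult:
    """Fit measured S^2(m) with a 1- or 2-exponential correlation function.

    ``trace`` must expose ``m``, ``s2_excess`` and ``histograms`` (see
    :class:`trbva.variance.TrbvaTrace`). The chi-square is the unweighted
    sum of squared differences over the m grid. The optimiser is bounded
    trust-region least squares, multi-started from ``n_starts`` log-spaced
    rates spanning 1e-3 to 1e3 /ms; the best chi-square wins, ties broken
    by the smaller rate. ``weights`` (optional, e.g. inverse bootstrap
    standard deviations per m) multiply the residuals; the default is the
    plain unweighted chi-square.
    """
    if n_exponentials not in (1, 2):
        raise ValueError("n_exponentials must be 1 or 2")
    m = np.asarray(trace.m)
    s2 = np.asarray(trace.s2_excess, dtype=float)
    hists = trace.histograms
    w = np.ones_like(s2) if weights is None else np.asarray(weights, float)
    ok = np.isfinite(s2) & np.isfinite(w)
    m, s2, w = m[ok], s2[ok], w[ok]
    hists = [h for h, k in zip(hists, ok) if k]
    n_par = 2 * n_exponentials
    if m.size < 2 * n_par:
        raise ValueError("too few trace points for the requested model")

    def model_s2(params):
        amps = params[:n_exponentials]
        lams = 10.0 ** params[n_exponentials:]
        corr = ExponentialCorrelation(amps, lams)
        return predict_s2(hists, corr)

    def resid(params):
        return w * (model_s2(params) - s2)

    a0 = float(np.clip(np.nanmax(s2), 1e-6, 0.25))
    lo = np.array([0.0] * n_exponentials + [_LOG_LAM_LO] * n_exponentials)
    hi = np.array([0.25] * n_exponentials + [_LOG_LAM_HI] * n_exponentials)
    if bounds:
        if "amplitude" in bounds:
            lo[:n_exponentials], hi[:n_exponentials] = bounds["amplitude"]
        if "rate" in bounds:
            lo[n_exponentials:] = np.log10(bounds["rate"][0])
            hi[n_exponentials:] = np.log10(bounds["rate"][1])

    starts = []
    if start is not None:
        p0 = np.concatenate([
            np.atleast_1d(np.asarray(start["amplitude"], float)),
            np.log10(np.atleast_1d(np.asarray(start["rate"], float))),
        ])
        starts.append(p0)
    grid = np.linspace(max(-6.0, lo[-1]), min(0.0, hi[-1]), n_starts)
    for lg in grid:
        if n_exponentials == 1:
            starts.append(np.array([a0, lg]))
        else:
            for lg2 in (lg + 1.0, lg + 2.0):
                if lg2 <= hi[-1]:
                    starts.append(np.array([a0 / 2, a0 / 2, lg, lg2]))

    best = None
    messages = []
    for p0 in starts:
        p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception as exc:  # pragma: no cover - solver pathologies
            messages.append(str(exc))
            continue
        cost = 2 * sol.cost
        lam_min = 10.0 ** np.min(sol.x[n_exponentials:])
        if best is None or cost < best[0] * (1 - 1e-12) or (
                abs(cost - best[0]) <= 1e-12 * max(best[0], 1e-300)
                and lam_min < best[1]):
            best = (cost, lam_min, sol)
    if best is None:
        raise RuntimeError("trace fit failed from every start")
    cost, _, sol = best
    amps = sol.x[:n_exponentials]
    lams = 10.0 ** sol.x[n_exponentials:]
    order = np.argsort(lams)
    amps, lams = amps[order], lams[order]
    at_bound = bool(
        np.any(np.abs(sol.x[n_exponentials:] - lo[n_exponentials:]) < 1e-6)
        or np.any(np.abs(sol.x[n_exponentials:] - hi[n_exponentials:]) < 1e-6)
    )
    if at_bound:
        messages.append("fitted rate at a bound; estimate unreliable")
    if not sol.success:
        messages.append("optimizer did not report convergence")
    s2_fit = model_s2(sol.x)
    return FitResult(
        amplitudes=amps,
        rates=lams,
        chisq=float(cost),
        residuals=s2 - s2_fit,
        m=m,
        s2_fit=s2_fit,
        n_exponentials=n_exponentials,
        converged=bool(sol.success),
        at_bound=at_bound,
        messages=messages,
    )
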
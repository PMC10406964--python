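"""The trBVA core: photon segments, excess variance, duration histograms.

Bursts are partitioned into consecutive, non-overlapping segments of m
donor-excitation photons (raw counts, no corrections). Each burst i
contributes floor(n_i/m) segments; trailing photons are discarded and
segments never wrap across bursts. For each segment the apparent FRET
efficiency eps = a/m (acceptor fraction) and the duration t (first-to-last
photon) are recorded. The pooled variance of eps over all segments,

    s2 = 1/(sum_i M_i - 1) * sum_ij (eps_ij - <eps>)^2,
    <eps> = sum_i a_i / sum_i n_i  (over the selected bursts),

is compared with the shot-noise expectation sigma2 = <eps>(1-<eps>)/m of a
single emitting state; the excess variance S2 = s2 - sigma2 is the trBVA
observable. Scanning m yields a trace S2(m) whose shape encodes the
timescale of conformational exchange; the per-m histogram of segment
durations H(t|m) is the empirical weight needed to predict S2(m) from a
kinetic model (see :mod:`trbva.kinetic_fit`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .photon_model import ACCEPTOR, DONOR_EX, Burst, PhotonStream
from . import kinetic_fit as kf

__all__ = [
    "SegmentSet",
    "TrbvaTrace",
    "burst_dex_photons",
    "segment_bursts",
    "segment_photon_sets",
    "excess_variance",
    "duration_histogram",
    "trbva_trace",
    "trace_from_photon_sets",
    "default_m_grid",
    "amplitude_profile",
    "AmplitudeProfile",
]


class UndefinedVarianceError(ValueError):
    """Fewer than two segments: the variance is undefined."""


@dataclass
class SegmentSet:
    """All m-photon segments pooled over the selected bursts."""

    m: int
    a: np.ndarray          # acceptor count per segment
    t: np.ndarray          # duration per segment, us (first-to-last photon)
    burst_id: np.ndarray   # index of the parent burst
    a_total: int           # sum of a_i over selected bursts (all Dex photons)
    n_total: int           # sum of n_i over selected bursts

    @property
    def eps(self) -> np.ndarray:
        """Apparent FRET efficiency per segment."""
        return self.a / self.m

    @property
    def n_segments(self) -> int:
        return int(self.a.size)


@dataclass
class TrbvaTrace:
    """Excess-variance trace over a grid of segment sizes m.

    ``histograms`` holds (m, bin centers, counts) per m — the empirical
    estimate of the segment-duration density P(t|m) used for fitting.
    """

    m: np.ndarray
    s2_total: np.ndarray    # pooled segment variance s2
    sigma2: np.ndarray      # shot-noise expectation
    s2_excess: np.ndarray   # S2 = s2 - sigma2
    n_segments: np.ndarray
    eps_mean: float
    histograms: list        # [(m, centers, counts), ...]


def burst_dex_photons(stream: PhotonStream, burst: Burst):
    """(times, is_acceptor) of a burst's donor-excitation photons."""
    sl = slice(burst.start, burst.stop)
    dex = stream.excitation[sl] == DONOR_EX
    times = stream.times[sl][dex]
    acc = stream.channel[sl][dex] == ACCEPTOR
    return times, acc


def segment_photon_sets(times_list: Sequence[np.ndarray],
                        acc_list: Sequence[np.ndarray],
                        m: int) -> SegmentSet:
    """Segment per-burst photon sequences into m-photon segments.

    ``times_list``/``acc_list`` hold, per burst, the macrotimes (us) and a
    boolean acceptor-channel flag of its donor-excitation photons, in time
    order.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    a_parts, t_parts, id_parts = [], [], []
    a_total = 0
    n_total = 0
    for b, (tt, aa) in enumerate(zip(times_list, acc_list)):
        n = tt.size
        a_total += int(np.count_nonzero(aa))
        n_total += int(n)
        M = n // m
        if M == 0:
            continue
        aa_m = np.asarray(aa[: M * m], dtype=np.int64).reshape(M, m)
        a_parts.append(aa_m.sum(axis=1))
        tt_m = tt[: M * m]
        t_parts.append(tt_m[m - 1:: m] - tt_m[0:: m])
        id_parts.append(np.full(M, b, dtype=np.int64))
    if a_parts:
        a = np.concatenate(a_parts)
        t = np.concatenate(t_parts)
        ids = np.concatenate(id_parts)
    else:
        a = np.empty(0, dtype=np.int64)
        t = np.empty(0)
        ids = np.empty(0, dtype=np.int64)
    return SegmentSet(m=m, a=a, t=t, burst_id=ids,
                      a_total=a_total, n_total=n_total)


def segment_bursts(bursts: Sequence[Burst], stream: PhotonStream,
                   m: int) -> SegmentSet:
    """Segment the donor-excitation photons of each burst (spec surface)."""
    pairs = [burst_dex_photons(stream, b) for b in bursts]
    times_list = [p[0] for p in pairs]
    acc_list = [p[1] for p in pairs]
    return segment_photon_sets(times_list, acc_list, m)


def excess_variance(segs: SegmentSet):
    """(s2, sigma2, S2) of a segment set.

    The sample variance uses denominator (sum M_i - 1); the pooled mean
    <eps> counts all donor-excitation photons of the selected bursts, not
    only segment-covered ones (the difference is O(m/n_i)).
    """
    if segs.n_segments < 2:
        raise UndefinedVarianceError(
            f"{segs.n_segments} segment(s) at m={segs.m}: variance undefined"
        )
    eps_mean = segs.a_total / segs.n_total
    dev = segs.eps - eps_mean
    s2 = float(np.sum(dev * dev) / (segs.n_segments - 1))
    sigma2 = eps_mean * (1.0 - eps_mean) / segs.m
    return s2, sigma2, s2 - sigma2


def duration_histogram(segs: SegmentSet, n_bins: int = 100):
    """Equally spaced histogram of segment durations on [0, max t].

    Returns (centers, counts); counts sum to the number of segments.
    """
    if segs.n_segments == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    tmax = float(segs.t.max())
    if tmax <= 0:
        tmax = 1.0
    counts, edges = np.histogram(segs.t, bins=n_bins, range=(0.0, tmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def default_m_grid(burst_sizes: np.ndarray, min_segments: int = 1000,
                   n_log: int = 12, m_cap: int = 1000) -> np.ndarray:
    """All integers 2..10, then log-spaced m up to the largest size at
    which at least ``min_segments`` segments survive."""
    burst_sizes = np.asarray(burst_sizes)
    m_max = 10
    for m in range(10, m_cap + 1):
        if np.sum(burst_sizes // m) < min_segments:
            break
        m_max = m
    grid = list(range(2, 11))
    if m_max > 10:
        grid += list(np.unique(np.geomspace(12, m_max, n_log).astype(int)))
    return np.unique(np.asarray(grid, dtype=int))


def trace_from_photon_sets(times_list, acc_list,
                           m_grid: Optional[np.ndarray] = None,
                           n_bins: int = 100,
                           min_segments: int = 2) -> TrbvaTrace:
    """Full trBVA trace for per-burst photon sequences."""
    if len(times_list) == 0:
        raise ValueError("no bursts selected")
    sizes = np.array([t.size for t in times_list])
    if m_grid is None:
        m_grid = default_m_grid(sizes)
    m_grid = np.asarray(sorted(set(int(m) for m in m_grid)))
    if np.any(m_grid < 2):
        raise ValueError("m must be >= 2")
    s2 = np.full(m_grid.size, np.nan)
    sig2 = np.full(m_grid.size, np.nan)
    S2 = np.full(m_grid.size, np.nan)
    nseg = np.zeros(m_grid.size, dtype=np.int64)
    hists = []
    eps_mean = np.nan
    for i, m in enumerate(m_grid):
        segs = segment_photon_sets(times_list, acc_list, int(m))
        nseg[i] = segs.n_segments
        if segs.n_segments < max(min_segments, 2):
            hists.append((int(m), np.empty(0), np.empty(0, dtype=np.int64)))
            continue
        s2[i], sig2[i], S2[i] = excess_variance(segs)
        centers, counts = duration_histogram(segs, n_bins)
        hists.append((int(m), centers, counts))
        eps_mean = segs.a_total / segs.n_total
    return TrbvaTrace(m=m_grid, s2_total=s2, sigma2=sig2, s2_excess=S2,
                      n_segments=nseg, eps_mean=float(eps_mean),
                      histograms=hists)


def trbva_trace(bursts: Sequence[Burst], stream: PhotonStream,
                m_grid: Optional[np.ndarray] = None,
                n_bins: int = 100) -> TrbvaTrace:
    """Spec surface: trace from a burst list plus its photon stream."""
    pairs = [burst_dex_photons(stream, b) for b in bursts]
    return trace_from_photon_sets([p[0] for p in pairs],
                                  [p[1] for p in pairs],
                                  m_grid=m_grid, n_bins=n_bins)


def bootstrap_trace(times_list, acc_list, m_grid, n_boot: int = 200,
                    rng=None):
    """Burst-level bootstrap of S^2(m): returns (mean, std) over resamples.

    The per-dataset analogue of repeating independent simulations; feeds
    the optional inverse-variance weighting of the kinetic fit.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = len(times_list)
    m_grid = np.asarray(m_grid)
    vals = np.full((n_boot, m_grid.size), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        tr = trace_from_photon_sets([times_list[i] for i in idx],
                                    [acc_list[i] for i in idx],
                                    m_grid=m_grid)
        vals[b] = tr.s2_excess
    return np.nanmean(vals, axis=0), np.nanstd(vals, axis=0)


@dataclass
class AmplitudeProfile:
    """FRET-resolved amplitude profile and its polynomial-root analysis."""

    centers: np.ndarray      # mean raw eps per window
    amplitudes: np.ndarray   # fitted <d eps^2> per window
    rates: np.ndarray        # fitted k_obs per window, 1/us
    n_bursts: np.ndarray
    roots: np.ndarray        # estimated eps1, eps2 (may be complex -> NaN)
    poly_sum: float          # eps1 + eps2
    poly_prod: float         # eps1 * eps2


def amplitude_profile(times_list, acc_list,
                      windows: Optional[np.ndarray] = None,
                      window_width: float = 0.05,
                      min_bursts: int = 30,
                      m_grid: Optional[np.ndarray] = None,
                      n_bins: int = 100) -> AmplitudeProfile:
    """Windowed trBVA amplitudes vs mean apparent FRET, with root recovery.

    Bursts are grouped by their raw proximity ratio into windows of width
    ``window_width`` (or explicit ``windows`` edges). Each window's trace
    is fitted with a single-exponential correlation function; the fitted
    amplitudes follow <d eps^2>(eps) = -(eps - eps1)(eps - eps2), a
    second-order polynomial with leading coefficient -1 whose roots locate
    the apparent FRET efficiencies of the two exchanging states. The
    polynomial is fitted linearly in (eps1 + eps2) and (eps1 * eps2).
    """
    eps_burst = np.array([
        (np.count_nonzero(a) / t.size) if t.size else np.nan
        for t, a in zip(times_list, acc_list)
    ])
    if windows is None:
        lo = np.floor(np.nanmin(eps_burst) / window_width) * window_width
        hi = np.ceil(np.nanmax(eps_burst) / window_width) * window_width
        windows = np.arange(lo, hi + window_width / 2, window_width)
    windows = np.asarray(windows)
    centers, amps, rates, counts = [], [], [], []
    for wlo, whi in zip(windows[:-1], windows[1:]):
        sel = np.flatnonzero((eps_burst >= wlo) & (eps_burst < whi))
        if sel.size < min_bursts:
            continue
        tl = [times_list[i] for i in sel]
        al = [acc_list[i] for i in sel]
        try:
            tr = trace_from_photon_sets(tl, al, m_grid=m_grid, n_bins=n_bins,
                                        min_segments=50)
            fit = kf.fit_trace(tr, n_exponentials=1)
        except (ValueError, RuntimeError):
            continue
        centers.append(float(np.mean(eps_burst[sel])))
        amps.append(float(fit.amplitudes[0]))
        rates.append(float(fit.rates[0]))
        counts.append(sel.size)
    centers = np.asarray(centers)
    amps = np.asarray(amps)
    if centers.size < 3:
        raise ValueError("too few populated FRET windows for a profile")
    # A = -c^2 + S c - P  ->  linear least squares for S, P
    X = np.column_stack([centers, -np.ones_like(centers)])
    y = amps + centers ** 2
    (S, P), *_ = np.linalg.lstsq(X, y, rcond=None)
    disc = S * S - 4 * P
    if disc >= 0:
        r = np.sort(np.array([(S - np.sqrt(disc)) / 2, (S + np.sqrt(disc)) / 2]))
    else:
        r = np.array([np.nan, np.nan])
    return AmplitudeProfile(centers=centers, amplitudes=amps,
                            rates=np.asarray(rates),
                            n_bursts=np.asarray(counts, dtype=int),
                            roots=r, poly_sum=float(S), poly_prod=float(P))
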
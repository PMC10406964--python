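"""Burst search, corrections and PIE-based filtering.

A burst is a maximal run of consecutive fixed-width time bins (default
100 us) that each contain more than two photons, retained when its total
donor-excitation photon count reaches a minimum (default 100). Burst-wise
corrected counts follow the community-standard order: background
subtraction (scaled by the burst duration), leakage subtraction
(nDA -= beta * nDD), direct-excitation subtraction (nDA -= alpha * nAA),
then the gamma factor applied to the donor channel (nDD *= gamma). The
corrected FRET efficiency is E = nDA / (nDA + nDD).

Two PIE filters vet the burst list: the stoichiometry
S_PIE = (nDD + nDA) / (nDD + nDA + gamma_PIE * nAA) rejects donor-only
molecules (S_PIE >= 0.65), and the detection-time asymmetry
alpha_PIE = <t_Dex> - <t_Aex> (in ms), compared against its shot-noise
standard deviation sigma_PIE = (T / (2 sqrt(3))) *
sqrt(1/(n'DD + n'DA) + 1/n'AA), rejects bursts in which the acceptor
bleached mid-transit. The default keeps a burst when sigma_PIE < 0.15 ms
and |alpha_PIE| <= 2 sigma_PIE; alternative cuts are selectable because
the combination of the two thresholds is an interpretation choice (see
docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .photon_model import (ACCEPTOR, ACCEPTOR_EX, DONOR, DONOR_EX, Burst,
                           PhotonStream)

__all__ = [
    "BurstSearchConfig",
    "CorrectionParams",
    "find_bursts",
    "correct_burst",
    "apply_corrections",
    "stoichiometry_filter",
    "bleaching_filter",
    "select_by_fret",
    "process_stream",
]

_SQRT12 = 2.0 * math.sqrt(3.0)


@dataclass
class BurstSearchConfig:
    bin_width: float = 100.0        # us
    min_photons_per_bin: int = 3    # "more than two photons per bin"
    min_total_photons: int = 100    # donor-excitation photons per burst
    count_dex_only: bool = False    # restrict the per-bin count to Dex photons

    def __post_init__(self):
        if min(self.bin_width, self.min_photons_per_bin,
               self.min_total_photons) <= 0:
            raise ValueError("all burst-search parameters must be positive")


@dataclass
class CorrectionParams:
    """Correction factors and background rates (per us, per class)."""

    gamma: float = 1.16
    leakage: float = 0.054
    direct_excitation: float = 0.048
    gamma_pie: float = 2.0
    bg_dd: float = 0.0   # donor channel, donor excitation
    bg_da: float = 0.0   # acceptor channel, donor excitation
    bg_aa: float = 0.0   # acceptor channel, acceptor excitation

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def from_detection(cls, det) -> "CorrectionParams":
        """Derive from a simulator DetectionConfig: channel backgrounds are
        split evenly between the two excitation half-periods."""
        return cls(gamma=det.gamma, leakage=det.leakage,
                   direct_excitation=det.direct_excitation,
                   gamma_pie=det.gamma_pie,
                   bg_dd=det.lambda_d / 2.0,
                   bg_da=det.lambda_a / 2.0,
                   bg_aa=det.lambda_a / 2.0)


def find_bursts(stream: PhotonStream,
                cfg: BurstSearchConfig = BurstSearchConfig()) -> List[Burst]:
    """Locate bursts as runs of consecutive occupied bins.

    Burst boundaries never split a bin, and bursts are disjoint in time.
    Raw counts split by (channel, excitation) plus time-sum accumulators
    for the PIE asymmetry are attached to each burst.
    """
    t = stream.times
    if t.size == 0:
        return []
    bw = cfg.bin_width
    if cfg.count_dex_only:
        t_count = t[stream.excitation == DONOR_EX]
    else:
        t_count = t
    n_bins = int(math.floor(stream.duration_s * 1e6 / bw)) + 1
    counts = np.bincount((t_count / bw).astype(np.int64), minlength=n_bins)
    good = counts >= cfg.min_photons_per_bin
    # run boundaries of the good-bin mask
    edges = np.diff(np.concatenate([[0], good.view(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)

    is_dex = stream.excitation == DONOR_EX
    is_aex = ~is_dex
    acc = stream.channel == ACCEPTOR
    cum_dd = np.concatenate([[0], np.cumsum(is_dex & ~acc)])
    cum_da = np.concatenate([[0], np.cumsum(is_dex & acc)])
    cum_aa = np.concatenate([[0], np.cumsum(is_aex & acc)])
    cum_aex = np.concatenate([[0], np.cumsum(is_aex)])
    cum_t_dex = np.concatenate([[0.0], np.cumsum(np.where(is_dex, t, 0.0))])
    cum_t_aex = np.concatenate([[0.0], np.cumsum(np.where(is_aex, t, 0.0))])

    bursts: List[Burst] = []
    i0s = np.searchsorted(t, starts * bw, side="left")
    i1s = np.searchsorted(t, stops * bw, side="left")
    for i0, i1 in zip(i0s, i1s):
        if i1 <= i0:
            continue
        n_dd = int(cum_dd[i1] - cum_dd[i0])
        n_da = int(cum_da[i1] - cum_da[i0])
        if n_dd + n_da < cfg.min_total_photons:
            continue
        bursts.append(Burst(
            start=int(i0), stop=int(i1),
            t_start=float(t[i0]), t_stop=float(t[i1 - 1]),
            n_dd_raw=n_dd, n_da_raw=n_da,
            n_aa_raw=int(cum_aa[i1] - cum_aa[i0]),
            n_aex_raw=int(cum_aex[i1] - cum_aex[i0]),
            sum_t_dex=float(cum_t_dex[i1] - cum_t_dex[i0]),
            sum_t_aex=float(cum_t_aex[i1] - cum_t_aex[i0]),
        ))
    return bursts


def correct_burst(b: Burst, p: CorrectionParams,
                  burst_duration_ms: float | None = None) -> Burst:
    """Fill in corrected counts, E and the PIE diagnostics (in place).

    Correction order: background -> leakage -> direct excitation -> gamma.
    Negative corrected counts are clamped at zero and flagged.
    """
    t_us = (burst_duration_ms * 1e3 if burst_duration_ms is not None
            else b.duration_us)
    n_dd = b.n_dd_raw - p.bg_dd * t_us
    n_da = b.n_da_raw - p.bg_da * t_us
    n_aa = b.n_aa_raw - p.bg_aa * t_us
    n_da = n_da - p.leakage * n_dd
    n_da = n_da - p.direct_excitation * n_aa
    n_dd = p.gamma * n_dd
    clamped = bool(n_dd < 0 or n_da < 0 or n_aa < 0)
    n_dd, n_da, n_aa = max(n_dd, 0.0), max(n_da, 0.0), max(n_aa, 0.0)
    b.n_dd, b.n_da, b.n_aa = n_dd, n_da, n_aa
    b.clamped = clamped
    tot = n_dd + n_da
    b.E = n_da / tot if tot > 0 else np.nan
    denom = tot + p.gamma_pie * n_aa
    b.s_pie = tot / denom if denom > 0 else np.nan
    n_dex = b.n_dd_raw + b.n_da_raw
    if n_dex > 0 and b.n_aex_raw > 0:
        b.alpha_pie = (b.sum_t_dex / n_dex - b.sum_t_aex / b.n_aex_raw) * 1e-3
    else:
        b.alpha_pie = np.nan
    if b.n_aa_raw > 0 and n_dex > 0:
        b.sigma_pie = (t_us * 1e-3 / _SQRT12) * math.sqrt(
            1.0 / n_dex + 1.0 / b.n_aa_raw)
    else:
        b.sigma_pie = np.inf
    return b


def apply_corrections(bursts: Sequence[Burst],
                      p: CorrectionParams) -> List[Burst]:
    return [correct_burst(b, p) for b in bursts]


def stoichiometry_filter(b: Burst, gamma_pie: float | None = None,
                         threshold: float = 0.65) -> bool:
    """Keep the burst iff S_PIE < threshold (rejects donor-only species).

    A zero denominator (no photons at all after correction) discards.
    """
    s = b.s_pie
    if gamma_pie is not None:
        tot = b.n_dd + b.n_da
        denom = tot + gamma_pie * b.n_aa
        s = tot / denom if denom > 0 else np.nan
    if not np.isfinite(s):
        return False
    return bool(s < threshold)


def bleaching_filter(b: Burst, sigma_threshold: float = 0.15,
                     alpha_sigma_factor: float = 2.0,
                     mode: str = "sigma_and_alpha") -> bool:
    """Keep the burst iff the PIE detection-time asymmetry is consistent
    with shot noise (no mid-burst acceptor bleach).

    Modes: ``sigma_and_alpha`` (default) requires sigma_PIE <
    ``sigma_threshold`` (ms) and |alpha_PIE| <= ``alpha_sigma_factor`` *
    sigma_PIE; ``sigma_only`` and ``alpha_only`` apply one cut alone.
    Bursts without acceptor-excitation photons discard.
    """
    if not np.isfinite(b.sigma_pie) or not np.isfinite(b.alpha_pie):
        return False
    sigma_ok = b.sigma_pie < sigma_threshold
    alpha_ok = abs(b.alpha_pie) <= alpha_sigma_factor * b.sigma_pie
    if mode == "sigma_only":
        return bool(sigma_ok)
    if mode == "alpha_only":
        return bool(alpha_ok)
    if mode != "sigma_and_alpha":
        raise ValueError(f"unknown bleaching-filter mode {mode!r}")
    return bool(sigma_ok and alpha_ok)


def select_by_fret(bursts: Sequence[Burst], e_low: float,
                   e_high: float) -> List[Burst]:
    """Bursts with corrected efficiency E_low <= E < E_high."""
    return [b for b in bursts
            if np.isfinite(b.E) and e_low <= b.E < e_high]


def process_stream(stream: PhotonStream,
                   search: BurstSearchConfig = BurstSearchConfig(),
                   corrections: CorrectionParams = CorrectionParams(),
                   pie_filters: bool = True,
                   s_pie_threshold: float = 0.65,
                   sigma_threshold: float = 0.15,
                   bleach_mode: str = "sigma_and_alpha"):
    """Search, correct and (optionally) PIE-filter a stream.

    Returns (kept bursts, all bursts).
    """
    bursts = find_bursts(stream, search)
    apply_corrections(bursts, corrections)
    if not pie_filters:
        return bursts, bursts
    kept = [b for b in bursts
            if stoichiometry_filter(b, threshold=s_pie_threshold)
            and bleaching_filter(b, sigma_threshold=sigma_threshold,
                                 mode=bleach_mode)]
    return kept, bursts
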
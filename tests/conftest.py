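"""Shared fixtures and small independent oracles for the test suite."""

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ctmc_photon_bursts(rng, n_bursts, duration_us, rate_per_us,
                       k12, k21, e1, e2):
    """Diffusion-free oracle data: two-state CTMC color process sampled by
    a homogeneous Poisson photon process.

    Each pseudo-burst has fixed duration; the state starts from
    equilibrium; photons are colored acceptor with probability equal to the
    state's apparent FRET efficiency. Returns (times_list, acc_list) in the
    same layout the variance module consumes. Rates in 1/us.
    """
    p1 = k21 / (k12 + k21)
    times_list, acc_list = [], []
    for _ in range(n_bursts):
        # state trajectory by Gillespie jumps
        jumps = [0.0]
        states = [0 if rng.random() < p1 else 1]
        t = 0.0
        while t < duration_us:
            k_out = k12 if states[-1] == 0 else k21
            t += rng.exponential(1.0 / k_out)
            if t >= duration_us:
                break
            jumps.append(t)
            states.append(1 - states[-1])
        jumps = np.asarray(jumps)
        states = np.asarray(states)
        n_ph = rng.poisson(rate_per_us * duration_us)
        tt = np.sort(rng.random(n_ph) * duration_us)
        s_ph = states[np.searchsorted(jumps, tt, side="right") - 1]
        eps = np.where(s_ph == 0, e1, e2)
        aa = rng.random(n_ph) < eps
        times_list.append(tt)
        acc_list.append(aa)
    return times_list, acc_list


def bootstrap_s2(times_list, acc_list, m_grid, n_boot, rng):
    """Burst-level bootstrap of S^2(m); returns (mean, std) arrays."""
    from trbva.variance import trace_from_photon_sets

    n = len(times_list)
    vals = np.full((n_boot, len(m_grid)), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        tr = trace_from_photon_sets([times_list[i] for i in idx],
                                    [acc_list[i] for i in idx],
                                    m_grid=m_grid)
        vals[b] = tr.s2_excess
    return np.nanmean(vals, axis=0), np.nanstd(vals, axis=0)
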
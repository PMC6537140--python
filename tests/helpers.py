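"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's semi-analytic code paths: the gated
decay oracle works on a 1 ps grid with FFT circular convolution and
trapezoidal gate quadrature, and the rank-sum oracle enumerates every rank
assignment exhaustively.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

PERIOD_NS = 12.5


def wrapped_exp_samples(tau: float, n: int, period: float = PERIOD_NS) -> np.ndarray:
    """Pointwise samples of the unit-integral wrapped exponential; the
    sample on the discontinuity (t=0) is the mean of the two one-sided
    limits, which restores second-order quadrature accuracy."""
    dt = period / n
    t = np.arange(n) * dt
    norm = tau * (1.0 - np.exp(-period / tau))
    f = np.exp(-t / tau) / norm
    f[0] = 0.5 * (f[0] + np.exp(-period / tau) / norm)
    return f


def gaussian_irf_samples(
    center: float, sigma: float, n: int, period: float = PERIOD_NS
) -> np.ndarray:
    dt = period / n
    t = np.arange(n) * dt
    out = np.zeros(n)
    for k in range(-3, 4):
        out += np.exp(-0.5 * ((t - center + k * period) / sigma) ** 2)
    return out / (out.sum() * dt)


def brute_force_gated_decay(
    tau: float,
    delays,
    gate_width: float,
    irf_samples: np.ndarray,
    period: float = PERIOD_NS,
) -> np.ndarray:
    """1 ps-grid circular convolution + trapezoidal gate quadrature.

    ``irf_samples`` must be on the same fine grid (unit integral).  Delays
    and the gate width must be multiples of the grid step.
    """
    n = irf_samples.size
    dt = period / n
    f = wrapped_exp_samples(tau, n, period)
    conv = np.fft.irfft(np.fft.rfft(irf_samples) * np.fft.rfft(f)) * dt
    n_gate = int(round(gate_width / dt))
    out = []
    for d in np.atleast_1d(delays):
        idx = (np.arange(n_gate + 1) + int(round(d / dt))) % n
        vals = conv[idx]
        out.append((vals.sum() - 0.5 * (vals[0] + vals[-1])) * dt)
    return np.array(out)


def brute_force_unwrapped_gated_decay(
    tau: float,
    delays,
    gate_width: float,
    irf_samples: np.ndarray,
    period: float = PERIOD_NS,
) -> np.ndarray:
    """Single-pulse (no pile-up) variant: line convolution on [0, 4T)."""
    from scipy.signal import fftconvolve

    n = irf_samples.size
    dt = period / n
    t = np.arange(4 * n) * dt
    f = np.exp(-t / tau) / tau
    irf_ext = np.concatenate([irf_samples, np.zeros(3 * n)])
    conv = fftconvolve(irf_ext, f)[: 4 * n] * dt
    n_gate = int(round(gate_width / dt))
    out = []
    for d in np.atleast_1d(delays):
        idx = np.arange(n_gate + 1) + int(round(d / dt))
        vals = conv[idx]
        out.append((vals.sum() - 0.5 * (vals[0] + vals[-1])) * dt)
    return np.array(out)


def exact_ranksum_pvalue(x, y) -> float:
    """Two-sided rank-sum p-value by exhaustive enumeration of all
    C(n1+n2, n1) assignments of ranks to the first sample (no ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    w_obs = ranks[: x.size].sum()
    n = pooled.size
    ws = np.array([sum(c) for c in combinations(range(1, n + 1), x.size)])
    mean = ws.mean()
    p = np.mean(np.abs(ws - mean) >= abs(w_obs - mean) - 1e-12)
    return float(p)
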
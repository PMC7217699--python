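"""Independent reference implementations used as test oracles.

These deliberately avoid the package's code paths (and scipy's peak
machinery): the NVC filter chain is re-derived from its printed
definition with explicit loops, and the deterministic simulator is a
plain-float recurrence.
"""

from __future__ import annotations

import math

import numpy as np


def detrend_linear(x):
    """Least-squares line removal via the normal equations."""
    n = len(x)
    t = np.arange(n, dtype=float)
    tbar = t.mean()
    xbar = np.mean(x)
    b = np.sum((t - tbar) * (x - xbar)) / np.sum((t - tbar) ** 2)
    a = xbar - b * tbar
    return np.asarray(x, dtype=float) - (a + b * t)


def _prominence_and_bases(x, i):
    n = len(x)
    # walk left to the nearest strictly-higher sample (or the border)
    j = i - 1
    left_min = x[i]
    while j >= 0 and x[j] <= x[i]:
        left_min = min(left_min, x[j])
        j -= 1
    j = i + 1
    right_min = x[i]
    while j < n and x[j] <= x[i]:
        right_min = min(right_min, x[j])
        j += 1
    return x[i] - max(left_min, right_min)


def _width_at_half_prominence(x, i, prom):
    level = x[i] - 0.5 * prom
    # left crossing, bounded by the prominence base region
    j = i
    while j > 0 and x[j - 1] >= level and x[j - 1] <= x[i]:
        j -= 1
    if j > 0 and x[j - 1] < level:
        frac = (x[j] - level) / (x[j] - x[j - 1])
        left = j - frac
    else:
        left = float(j)
    k = i
    n = len(x)
    while k < n - 1 and x[k + 1] >= level and x[k + 1] <= x[i]:
        k += 1
    if k < n - 1 and x[k + 1] < level:
        frac = (x[k] - level) / (x[k] - x[k + 1])
        right = k + frac
    else:
        right = float(k)
    return right - left


def brute_force_nvcs(samples, rate, amp_min=0.1, amp_max=4.0, width_lo=1.5, width_hi=8.0, separation=5.0):
    """Printed NVC criteria applied literally to one (intervoid) segment.

    Returns a list of (index, amplitude, width_s) tuples after linear
    detrend, strict local-maximum search, prominence and half-prominence
    width filters, and the greedy larger-first/earlier-first 5 s
    isolation rule.
    """
    x = detrend_linear(samples)
    n = len(x)
    cands = []
    for i in range(1, n - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            prom = _prominence_and_bases(x, i)
            if not (amp_min <= prom <= amp_max):
                continue
            w = _width_at_half_prominence(x, i, prom) / rate
            if not (width_lo <= w <= width_hi):
                continue
            cands.append((i, prom, w))
    # isolation: larger amplitude wins, ties to the earlier peak
    chosen = []
    for i, prom, w in sorted(cands, key=lambda c: (-c[1], c[0])):
        if all(abs(i - j) / rate >= separation for j, _, _ in chosen):
            chosen.append((i, prom, w))
    return sorted(chosen)


def deterministic_recurrence(params, n_steps):
    """Plain-float re-statement of the zero-variance feedback loop.

    With the firing variance suppressed, every quantity follows a
    closed-form recurrence; this mirrors the published update rules
    directly without the package's state machinery.
    """
    base = 0.0
    p = 0.0
    queue = [0.0] * params.bump_duration
    filling = True
    ps, ss = [], []
    voids = []
    for t in range(1, n_steps + 1):
        if filling:
            base += params.infusion_step
            active = queue.pop(0)
            queue.append(0.0)
            p = base + active
            smax = params.fmin + (params.fmax - params.fmin) / (
                1.0 + math.exp(-params.ks * (p - params.ms))
            )
            s = smax / 2.0
            dpmax = max(0.0, params.dPmax_coeff * math.log10(p)) if p > 0 else 0.0
            amp = params.dP_min + (dpmax - params.dP_min) / (
                1.0 + math.exp(-params.kp * (s - params.mp))
            )
            for k in range(params.bump_duration):
                off = (k + 1) * params.dt
                queue[k] += amp * math.exp(
                    -((off - params.bump_peak_offset) ** 2) / (2.0 * params.bump_variance)
                )
            if p >= params.void_threshold:
                filling = False
                voids.append(t - 1)
                queue = [0.0] * params.bump_duration
        else:
            p = max(0.0, p - params.emptying_step)
            base = p
            s = params.fmin
            if p < params.basal_reset:
                filling = True
        ps.append(p)
        ss.append(s)
    return np.array(ps), np.array(ss), voids
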
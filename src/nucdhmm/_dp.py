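"""Log-space dynamic-programming kernels for the duration HMM.

The recursions are O(n * tau_L) time and O(n) memory; they are compiled with
numba when available and fall back to the same pure-Python code otherwise.
All positional arrays are 1-based (index 0 = virtual origin).

State conventions (N = nucleosome, fixed 147 bp; L = linker, 1..tau_L bp):

* ``aN[i]``: log-probability of x_1..x_i summed over paths in which a
  nucleosome block ends exactly at i (``aN[0] = 0`` is the virtual origin, so
  the first real block must be a linker);
* ``aL[i]``: same with a linker block ending at i; the chain must end in a
  linker, so ``log P(x) = aL[n]``;
* ``bN[i]`` / ``bL[i]``: log-probability of x_{i+1}..x_n given a nucleosome /
  linker block ended at i; ``log P(x) = bN[0]``.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

NEG_INF = -np.inf
NUC_LEN = 147


@njit(cache=False)
def _linkll(SW, SD, Wc, Cc, o, a, b):
    k = b - a + 1
    m = o if k > o else k
    return (SW[b] - SW[a - 1] - Wc[m, a]
            + SD[b] - SD[a - 1] - Cc[m, b])


@njit(cache=False)
def _forward(en1, lf, SW, SD, Wc, Cc, o, tau_l, n):
    aN = np.full(n + 1, NEG_INF)
    aL = np.full(n + 1, NEG_INF)
    aN[0] = 0.0
    for i in range(1, n + 1):
        if i >= NUC_LEN and aL[i - NUC_LEN] > NEG_INF:
            aN[i] = aL[i - NUC_LEN] + en1[i - NUC_LEN + 1]
        kmax = tau_l if tau_l < i else i
        m_run = NEG_INF
        s_run = 0.0
        base_i = SW[i] + SD[i]
        for k in range(1, kmax + 1):
            j = i - k
            anj = aN[j]
            if anj == NEG_INF:
                continue
            flk = lf[k - 1]
            if flk == NEG_INF:
                continue
            m = k if k < o else o
            t = (anj + flk + base_i - SW[j] - SD[j]
                 - Wc[m, j + 1] - Cc[m, i])
            if t == NEG_INF:
                continue
            if t > m_run:
                s_run = s_run * math.exp(m_run - t) + 1.0
                m_run = t
            else:
                s_run += math.exp(t - m_run)
        if m_run > NEG_INF:
            aL[i] = m_run + math.log(s_run)
    return aN, aL


@njit(cache=False)
def _backward(en1, lf, SW, SD, Wc, Cc, o, tau_l, n):
    bN = np.full(n + 1, NEG_INF)
    bL = np.full(n + 1, NEG_INF)
    bL[n] = 0.0
    for i in range(n, -1, -1):
        if i < n and i + NUC_LEN <= n and bN[i + NUC_LEN] > NEG_INF:
            e = en1[i + 1]
            if e > NEG_INF:
                bL[i] = e + bN[i + NUC_LEN]
        kmax = tau_l if tau_l < n - i else n - i
        m_run = NEG_INF
        s_run = 0.0
        for k in range(1, kmax + 1):
            blv = bL[i + k]
            if blv == NEG_INF:
                continue
            flk = lf[k - 1]
            if flk == NEG_INF:
                continue
            t = flk + _linkll(SW, SD, Wc, Cc, o, i + 1, i + k) + blv
            if t == NEG_INF:
                continue
            if t > m_run:
                s_run = s_run * math.exp(m_run - t) + 1.0
                m_run = t
            else:
                s_run += math.exp(t - m_run)
        if m_run > NEG_INF:
            bN[i] = m_run + math.log(s_run)
    return bN, bL


@njit(cache=False)
def _viterbi_fill(en1, lf, SW, SD, Wc, Cc, o, tau_l, n):
    vN = np.full(n + 1, NEG_INF)
    vL = np.full(n + 1, NEG_INF)
    bp = np.zeros(n + 1, dtype=np.int32)
    vN[0] = 0.0
    for i in range(1, n + 1):
        if i >= NUC_LEN and vL[i - NUC_LEN] > NEG_INF:
            vN[i] = vL[i - NUC_LEN] + en1[i - NUC_LEN + 1]
        kmax = tau_l if tau_l < i else i
        best = NEG_INF
        bestk = 0
        base_i = SW[i] + SD[i]
        for k in range(1, kmax + 1):
            j = i - k
            vnj = vN[j]
            if vnj == NEG_INF:
                continue
            flk = lf[k - 1]
            if flk == NEG_INF:
                continue
            m = k if k < o else o
            t = (vnj + flk + base_i - SW[j] - SD[j]
                 - Wc[m, j + 1] - Cc[m, i])
            if t > best:  # strict: ties keep the smaller k
                best = t
                bestk = k
        if bestk > 0:
            vL[i] = best
            bp[i] = bestk
    return vN, vL, bp


@njit(cache=False)
def _expected_linker_counts(aN, bL, lf, SW, SD, Wc, Cc, o, tau_l, n, logp):
    out = np.zeros(tau_l)
    for k in range(1, tau_l + 1):
        flk = lf[k - 1]
        if flk == NEG_INF:
            continue
        acc = 0.0
        for i in range(k, n + 1):
            anj = aN[i - k]
            if anj == NEG_INF:
                continue
            blv = bL[i]
            if blv == NEG_INF:
                continue
            t = anj + flk + _linkll(SW, SD, Wc, Cc, o, i - k + 1, i) + blv - logp
            acc += math.exp(t)
        out[k - 1] = acc
    return out
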
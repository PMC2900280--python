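"""Independent brute-force reference implementations used as test oracles.

Everything here deliberately avoids the package's dynamic programming and
vectorized code paths: likelihoods are naive per-position products,
posterior quantities come from exhaustive enumeration of all valid
segmentations, and matchers/peak callers are direct quadratic scans.
"""

import math

import numpy as np

from nucdhmm.models import (BASES, NUC_LEN, history_to_code, linker_loglik,
                            nucleosome_loglik)


def naive_strand_loglik_nuc(seq, model):
    """Single-strand nucleosome log-likelihood via explicit table lookups."""
    idx = [BASES.index(c) for c in seq]
    total = 0.0
    for p in range(NUC_LEN):
        h = min(p, model.order)
        tab = model.init[p] if p < model.order else model.body[p - model.order]
        pr = tab[history_to_code(idx[p - h:p]), idx[p]]
        if pr == 0:
            return -math.inf
        total += math.log(pr)
    return total


def naive_strand_loglik_link(seq, model):
    idx = [BASES.index(c) for c in seq]
    total = 0.0
    for i in range(len(idx)):
        h = min(i, model.order)
        tab = model.stationary[None, :] if h == 0 else model.cond[h - 1]
        pr = tab[history_to_code(idx[i - h:i]) if h else 0, idx[i]]
        if pr == 0:
            return -math.inf
        total += math.log(pr)
    return total


def compositions(total, parts, tau):
    """All ways to write ``total`` as ``parts`` ordered terms in [1, tau]."""
    if parts == 1:
        if 1 <= total <= tau:
            yield (total,)
        return
    for k in range(1, min(tau, total - (parts - 1)) + 1):
        for rest in compositions(total - k, parts - 1, tau):
            yield (k,) + rest


def enumerate_segmentations(n, tau):
    """Yield linker-length tuples (k_0..k_m) of every valid L N L ... L path."""
    for m in range(n // NUC_LEN + 1):
        rem = n - m * NUC_LEN
        if rem < m + 1 or rem > tau * (m + 1):
            continue
        yield from compositions(rem, m + 1, tau)


def brute_force_posteriors(seq, nuc, link, F):
    """Exhaustive-path log P(x), occupancy, E(n_k|x), and the best path.

    Returns None when no segmentation has positive probability.  The best
    path is reported as the list of 1-based nucleosome starts; ties keep the
    lexicographically smallest linker tuple (matching smallest-k Viterbi
    tie-breaking).
    """
    n = len(seq)
    tau = F.tau_l
    logps, paths = [], []
    for ks in enumerate_segmentations(n, tau):
        lp = 0.0
        pos = 0
        starts = []
        ok = True
        for j, k in enumerate(ks):
            if F.pmf[k - 1] <= 0:
                ok = False
                break
            lp += math.log(F.pmf[k - 1]) + linker_loglik(seq[pos:pos + k], link)
            pos += k
            if j < len(ks) - 1:
                lp += nucleosome_loglik(seq[pos:pos + NUC_LEN], nuc)
                starts.append(pos + 1)
                pos += NUC_LEN
        if ok and np.isfinite(lp):
            logps.append(lp)
            paths.append((ks, starts))
    if not logps:
        return None
    logps = np.asarray(logps)
    m = logps.max()
    logp = float(m + math.log(np.exp(logps - m).sum()))
    w = np.exp(logps - logp)
    occ = np.zeros(n)
    nk = np.zeros(tau)
    for wi, (ks, starts) in zip(w, paths):
        for s in starts:
            occ[s - 1:s - 1 + NUC_LEN] += wi
        for k in ks:
            nk[k - 1] += wi
    best = min(range(len(paths)), key=lambda i: (-logps[i], paths[i][0]))
    return {"loglik": logp, "occupancy": occ, "linker_counts": nk,
            "viterbi_starts": paths[best][1], "viterbi_loglik": float(logps[best])}


def brute_match(pred, true, tol):
    """O(n*m) sensitivity / FDR by direct pairwise distance checks."""
    pred = list(pred)
    true = list(true)
    hit_true = sum(1 for t in true if any(abs(t - p) <= tol for p in pred))
    sens = 100.0 * hit_true / len(true)
    if not pred:
        return sens, 0.0, 0
    false = sum(1 for p in pred if not any(abs(p - t) <= tol for t in true))
    return sens, 100.0 * false / len(pred), len(pred)


def brute_moving_average(vec, window):
    n = len(vec)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n - 1, i + half)
        out[i] = np.mean(vec[lo:hi + 1])
    return out


def brute_local_maxima(vec):
    """Plateau-collapsing local maxima by direct neighborhood inspection."""
    n = len(vec)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vec[j + 1] == vec[i]:
            j += 1
        left = vec[i - 1] if i > 0 else None
        right = vec[j + 1] if j < n - 1 else None
        left_ok = left is None or left < vec[i]
        right_ok = right is None or right < vec[i]
        strict = (left is not None and left < vec[i]) or \
                 (right is not None and right < vec[i])
        if left_ok and right_ok and strict:
            out.append(((i + j) // 2, float(vec[i])))
        i = j + 1
    return out


def brute_peak_thinning(cands, min_sep):
    """Survivors of iterated discard-the-smaller-conflict, by recursion.

    A candidate survives iff no surviving candidate with larger value (or
    equal value and smaller position) lies strictly within ``min_sep``.
    """
    order = sorted(cands, key=lambda pv: (-pv[1], pv[0]))
    survives = {}
    for p, v in order:
        killed = False
        for q, u in order:
            if (q, u) == (p, v):
                break
            if survives[(q, u)] and abs(p - q) < min_sep:
                killed = True
                break
        survives[(p, v)] = not killed
    return sorted(p for (p, _v), alive in survives.items() if alive)
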
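"""Vectorized per-position emission scores shared by all decoding routines.

The duration-HMM recursions need, for every position of the input sequence,

* ``en1[a]``: the both-strand nucleosome log-likelihood of the 147-bp window
  starting at position ``a`` (1-based), and
* the both-strand linker log-likelihood of an arbitrary standalone segment
  ``[a, b]`` in O(1), via cumulative per-position conditional log-probabilities
  plus start/end corrections for the first ``order`` positions of the segment
  (which must use shorter-history tables because a standalone linker has no
  context before its first base).

For the Watson strand the correction depends only on the segment start; for
the Crick strand (the reverse complement read right-to-left) it depends only
on the segment end.  ``linker_segment_loglik(a, b) =
SW[b]-SW[a-1]-Wc[m,a] + SD[b]-SD[a-1]-Cc[m,b]`` with ``m = min(order, b-a+1)``.

Every table lookup that involves an ambiguous base (as outcome or history)
contributes ln(0.25) per strand under both models, so ambiguity is neutral
and decoding around an N is driven entirely by flanking context.

All arrays here are 1-based (index 0 is padding) to match the positional
conventions of the decoding recursions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import LOG_QUARTER, NUC_LEN, LinkerModel, NucleosomeModel, encode


def _log(tab: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(tab)


def _context_codes(b1: np.ndarray, order: int):
    """Left-history codes/validity per history length m = 0..order.

    ``codeW[m][i]`` encodes bases at positions i-m..i-1 (oldest most
    significant); ``ambW[m][i]`` is True if any of them is ambiguous.  The
    entries at i <= m are never dereferenced by the callers.
    """
    n = len(b1) - 1
    bc = np.where(b1 >= 4, 0, b1).astype(np.int64)
    amb = b1 >= 4
    codeW = [np.zeros(n + 1, dtype=np.int64)]
    ambW = [np.zeros(n + 1, dtype=bool)]
    for m in range(1, order + 1):
        prev = codeW[m - 1]
        code = np.zeros(n + 1, dtype=np.int64)
        a = np.zeros(n + 1, dtype=bool)
        code[m:] = bc[:-m] * (4 ** (m - 1)) + prev[m:] - 0  # oldest base joins at top
        # prev[i] covers i-(m-1)..i-1; adding b[i-m] with weight 4**(m-1)
        a[m:] = ambW[m - 1][m:] | amb[:-m]
        codeW.append(code)
        ambW.append(a)
    return codeW, ambW


def _rcontext_codes(b1: np.ndarray, order: int):
    """Right-history codes for the Crick strand.

    ``codeC[m][i]`` encodes the complements of bases at i+1..i+m, with the
    complement of the base at i+m (the oldest on the Crick strand) most
    significant.  Entries at i > n-m are never dereferenced.
    """
    n = len(b1) - 1
    comp = np.where(b1 >= 4, 0, 3 - b1).astype(np.int64)
    amb = b1 >= 4
    codeC = [np.zeros(n + 1, dtype=np.int64)]
    ambC = [np.zeros(n + 1, dtype=bool)]
    for m in range(1, order + 1):
        prev = codeC[m - 1]
        code = np.zeros(n + 1, dtype=np.int64)
        a = np.zeros(n + 1, dtype=bool)
        code[:n + 1 - m] = comp[m:] * (4 ** (m - 1)) + prev[:n + 1 - m]
        a[:n + 1 - m] = ambC[m - 1][:n + 1 - m] | amb[m:]
        codeC.append(code)
        ambC.append(a)
    return codeC, ambC


def _lookup(logtab: np.ndarray, codes: np.ndarray, bases: np.ndarray,
            invalid: np.ndarray) -> np.ndarray:
    """Gather log-probabilities; any lookup touching ambiguity -> ln(0.25)."""
    bclip = np.where(bases >= 4, 0, bases)
    vals = logtab[codes, bclip]
    vals[invalid | (bases >= 4)] = LOG_QUARTER
    return vals


@dataclass
class Emissions:
    """Precomputed emission scores for one (sequence, model pair).

    Reusable across different linker-length distributions, which makes the
    iterative linker-length re-estimation cheap: only the DP recursions are
    re-run when ``F_L`` changes.
    """

    n: int
    order: int                 # linker-chain order (for segment corrections)
    en1: np.ndarray            # (A+1,) both-strand nucleosome scores, a=1..A
    SW: np.ndarray             # (n+1,) Watson cumulative full-order scores
    SD: np.ndarray             # (n+2,) Crick cumulative full-order scores
    Wc: np.ndarray             # (order+1, n+2) Watson start corrections
    Cc: np.ndarray             # (order+1, n+2) Crick end corrections

    def linker_segment_loglik(self, a, b):
        """Both-strand standalone linker log-likelihood of [a, b] (1-based)."""
        a = np.asarray(a)
        b = np.asarray(b)
        m = np.minimum(self.order, b - a + 1)
        return (self.SW[b] - self.SW[a - 1] - self.Wc[m, a]
                + self.SD[b] - self.SD[a - 1] - self.Cc[m, b])


def _linker_position_scores(b1: np.ndarray, link: LinkerModel):
    n = len(b1) - 1
    o = link.order
    codeW, ambW = _context_codes(b1, o)
    codeC, ambC = _rcontext_codes(b1, o)
    logtabs = [_log(link.table_for_history(h)) for h in range(o + 1)]

    idx = np.arange(n + 1)
    # h[m][i]: log qL(x_i | history of length m); g[m][i]: Crick analogue
    h = np.empty((o + 1, n + 1))
    g = np.empty((o + 1, n + 1))
    comp_b1 = np.where(b1 >= 4, 4, 3 - b1)
    for m in range(o + 1):
        tab = logtabs[m]
        h[m] = _lookup(tab, codeW[m], b1, ambW[m])
        g[m] = _lookup(tab, codeC[m], comp_b1, ambC[m])
    # full-order per-position scores with truncated-history placeholders at
    # the sequence boundaries (they cancel between cumsum and correction)
    c = h[o].copy()
    d = g[o].copy()
    for i in range(1, min(o, n) + 1):
        c[i] = h[i - 1][i]
    for i in range(max(1, n - o + 1), n + 1):
        d[i] = g[n - i][i]

    SW = np.zeros(n + 1)
    np.cumsum(c[1:], out=SW[1:])
    SD = np.zeros(n + 2)
    np.cumsum(d[1:], out=SD[1:n + 1])

    Wc = np.zeros((o + 1, n + 2))
    Cc = np.zeros((o + 1, n + 2))
    for m in range(1, o + 1):
        # Wc[m][a] = Wc[m-1][a] + (c - h[m-1]) at position a+m-1
        term = c - h[m - 1]
        Wc[m, 1:n - m + 2] = Wc[m - 1, 1:n - m + 2] + term[m:n + 1]
        term = d - g[m - 1]
        Cc[m, m:n + 1] = Cc[m - 1, m:n + 1] + term[1:n - m + 2]
    return SW, SD, Wc, Cc


def _nucleosome_window_scores(b1: np.ndarray, nuc: NucleosomeModel) -> np.ndarray:
    n = len(b1) - 1
    A = n - NUC_LEN + 1
    if A < 1:
        return np.full(1, -np.inf)
    o = nuc.order
    codeW, ambW = _context_codes(b1, o)
    codeC, ambC = _rcontext_codes(b1, o)
    comp_b1 = np.where(b1 >= 4, 4, 3 - b1)
    acc = np.zeros(A)
    for p in range(NUC_LEN):
        h = min(p, o)
        logtab = _log(nuc.table_for_position(p))
        iw = slice(1 + p, 1 + p + A)            # Watson: i = a + p
        acc += _lookup(logtab, codeW[h][iw], b1[iw], ambW[h][iw])
        ic = slice(NUC_LEN - p, NUC_LEN - p + A)  # Crick: i = a + 146 - p
        acc += _lookup(logtab, codeC[h][ic], comp_b1[ic], ambC[h][ic])
    en1 = np.empty(A + 1)
    en1[0] = -np.inf
    en1[1:] = acc
    return en1


def precompute(seq: str, nuc: NucleosomeModel, link: LinkerModel) -> Emissions:
    """Build the emission cache for a sequence under a model pair."""
    if len(seq) < 1:
        raise ValueError("sequence must be non-empty")
    b = encode(seq)
    b1 = np.empty(len(b) + 1, dtype=np.int8)
    b1[0] = 4
    b1[1:] = b
    SW, SD, Wc, Cc = _linker_position_scores(b1, link)
    en1 = _nucleosome_window_scores(b1, nuc)
    return Emissions(n=len(b), order=link.order, en1=en1,
                     SW=SW, SD=SD, Wc=Wc, Cc=Cc)
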
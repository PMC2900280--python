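"""Inference for the two-state nucleosome/linker duration HMM.

A hidden path segments the sequence into strictly alternating blocks
``L N L N ... N L``: it must start and end in a linker, every nucleosome
block is exactly 147 bp, and every linker block has length 1..tau_L with
prior mass ``F_L(k)``.  The joint probability of sequence and path is the
product of the block emission probabilities (both strands) and the linker
length probabilities.

Provided here: forward/backward in log space, the per-position occupancy
posterior ``o_i = P(z_i = 1 | x)``, Viterbi decoding of the most probable
positioning map, the histone-affinity log-likelihood-ratio track, and the
posterior expected linker-length counts used for re-estimating ``F_L``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import _dp
from .emission import Emissions, precompute
from .models import (NUC_LEN, LinkerLengthDistribution, LinkerModel,
                     NucleosomeModel)

_FB_TOL = 1e-6


class NoPathError(ValueError):
    """No valid alternating segmentation exists for this sequence length
    under the support of the linker-length distribution."""


@dataclass
class SequenceRecord:
    """A named DNA sequence (A/C/G/T plus IUPAC ambiguity codes)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError("sequence must be non-empty")


@dataclass
class StatePath:
    """An alternating linker/nucleosome segmentation.

    ``blocks`` is an ordered list of ``(state, start, length)`` with state in
    {"N", "L"}, 1-based starts, strictly alternating states, first and last
    blocks linkers, and nucleosome blocks of exactly 147 bp.
    """

    blocks: list

    @property
    def nucleosome_starts(self) -> np.ndarray:
        return np.array([s for st, s, _l in self.blocks if st == "N"], dtype=int)

    @property
    def nucleosome_centers(self) -> np.ndarray:
        """Dyad positions (start + 73, the center of the 147-bp wrap)."""
        return self.nucleosome_starts + 73

    def state_vector(self, n: int) -> np.ndarray:
        """0/1 per position (1 = covered by a nucleosome)."""
        z = np.zeros(n, dtype=np.int8)
        for st, s, l in self.blocks:
            if st == "N":
                z[s - 1:s - 1 + l] = 1
        return z

    def validate(self, n: int, tau_l: int) -> None:
        pos = 1
        for i, (st, s, l) in enumerate(self.blocks):
            if s != pos:
                raise ValueError("blocks must tile the sequence without gaps")
            if st == "N" and l != NUC_LEN:
                raise ValueError("nucleosome blocks must be 147 bp")
            if st == "L" and not (1 <= l <= tau_l):
                raise ValueError("linker length outside [1, tau_L]")
            if i > 0 and st == self.blocks[i - 1][0]:
                raise ValueError("states must strictly alternate")
            pos += l
        if pos != n + 1:
            raise ValueError("blocks must cover exactly [1, n]")
        if self.blocks[0][0] != "L" or self.blocks[-1][0] != "L":
            raise ValueError("path must start and end with a linker")


@dataclass
class ForwardBackward:
    """Forward/backward quantities at block-end resolution (log domain)."""

    em: Emissions
    F: LinkerLengthDistribution
    alpha_n: np.ndarray
    alpha_l: np.ndarray
    beta_n: np.ndarray
    beta_l: np.ndarray
    loglik: float            # alpha-side accumulation, log P(x) = aL[n]
    loglik_backward: float   # beta-side accumulation, log P(x) = bN[0]


@dataclass
class PredictionResult:
    """Per-record decoding output."""

    occupancy: np.ndarray    # o_i in [0, 1], length n
    viterbi: StatePath
    affinity: np.ndarray     # NaN where no full 147-bp window fits
    loglik: float


def _resolve_seq(seq) -> str:
    return seq.seq if isinstance(seq, SequenceRecord) else seq


def _get_em(seq, nuc, link, em: Optional[Emissions]) -> Emissions:
    if em is not None:
        return em
    if seq is None:
        raise ValueError("either a sequence or a precomputed Emissions is required")
    return precompute(_resolve_seq(seq), nuc, link)


def forward_backward(seq, nuc: NucleosomeModel = None, link: LinkerModel = None,
                     F: LinkerLengthDistribution = None, *,
                     em: Optional[Emissions] = None) -> ForwardBackward:
    """Run both recursions and return the block-end quantities.

    ``em`` may be supplied to reuse a precomputed emission cache (the cache
    is independent of ``F``, so iterative linker-length updates only pay for
    the DP).  Raises if the forward- and backward-derived log P(x) disagree
    beyond 1e-6.
    """
    if F is None:
        raise ValueError("a linker length distribution is required")
    if np.all(F.pmf == 0):
        raise ValueError("linker length distribution is all-zero")
    em = _get_em(seq, nuc, link, em)
    lf = F.log_pmf()
    args = (em.en1, lf, em.SW, em.SD, em.Wc, em.Cc, em.order, F.tau_l, em.n)
    a_n, a_l = _dp._forward(*args)
    b_n, b_l = _dp._backward(*args)
    ll_f, ll_b = float(a_l[em.n]), float(b_n[0])
    if np.isfinite(ll_f) or np.isfinite(ll_b):
        if abs(ll_f - ll_b) > _FB_TOL * max(1.0, abs(ll_f)):
            warnings.warn(
                f"forward/backward log-likelihood mismatch: {ll_f} vs {ll_b}")
    return ForwardBackward(em=em, F=F, alpha_n=a_n, alpha_l=a_l,
                           beta_n=b_n, beta_l=b_l,
                           loglik=ll_f, loglik_backward=ll_b)


def nucleosome_start_posteriors(fb: ForwardBackward) -> np.ndarray:
    """P(a nucleosome block starts at a | x) for a = 1..n-146 (index a-1)."""
    em, n = fb.em, fb.em.n
    A = n - NUC_LEN + 1
    if A < 1 or not np.isfinite(fb.loglik):
        return np.zeros(max(A, 0))
    lp = (fb.alpha_l[0:A] + fb.em.en1[1:A + 1]
          + fb.beta_n[NUC_LEN:n + 1] - fb.loglik)
    with np.errstate(invalid="ignore"):
        post = np.exp(lp)
    post[~np.isfinite(lp)] = 0.0
    return post


def occupancy(fb: ForwardBackward) -> np.ndarray:
    """Posterior probability that each position is covered by a nucleosome."""
    n = fb.em.n
    post = nucleosome_start_posteriors(fb)
    occ = np.zeros(n + 1)
    if post.size:
        diff = np.zeros(n + 2)
        starts = np.arange(1, len(post) + 1)
        np.add.at(diff, starts, post)
        np.add.at(diff, starts + NUC_LEN, -post)
        occ = np.cumsum(diff)[:n + 1]
    occ = occ[1:]
    dust = max(0.0, float(occ.max(initial=0.0)) - 1.0)
    if dust > 1e-6:
        warnings.warn(f"occupancy exceeded 1 by {dust:.3g} before clipping")
    return np.clip(occ, 0.0, 1.0)


def expected_nucleosome_count(fb: ForwardBackward) -> float:
    """Posterior expectation of the number of nucleosome blocks."""
    return float(nucleosome_start_posteriors(fb).sum())


def expected_linker_counts(fb: ForwardBackward,
                           F: LinkerLengthDistribution) -> np.ndarray:
    """Posterior expectation E(n_k | x) of the number of length-k linkers.

    ``F`` must be the distribution used to build ``fb``; summing over k gives
    the posterior expected number of linker blocks (one more than the
    expected number of nucleosomes).
    """
    if F is not fb.F and not np.array_equal(F.pmf, fb.F.pmf):
        raise ValueError("F does not match the distribution used for forward/backward")
    if not np.isfinite(fb.loglik):
        raise NoPathError("sequence has no valid segmentation")
    em = fb.em
    return _dp._expected_linker_counts(
        fb.alpha_n, fb.beta_l, F.log_pmf(), em.SW, em.SD, em.Wc, em.Cc,
        em.order, F.tau_l, em.n, fb.loglik)


def viterbi(seq, nuc: NucleosomeModel = None, link: LinkerModel = None,
            F: LinkerLengthDistribution = None, *,
            em: Optional[Emissions] = None) -> StatePath:
    """Most probable segmentation; ties broken toward the smaller linker length."""
    if F is None:
        raise ValueError("a linker length distribution is required")
    em = _get_em(seq, nuc, link, em)
    lf = F.log_pmf()
    _vN, vL, bp = _dp._viterbi_fill(em.en1, lf, em.SW, em.SD, em.Wc, em.Cc,
                                    em.order, F.tau_l, em.n)
    n = em.n
    if not np.isfinite(vL[n]):
        raise NoPathError(
            f"no valid segmentation of length {n} under the given F_L support")
    blocks = []
    i = n
    while i > 0:
        k = int(bp[i])
        blocks.append(("L", i - k + 1, k))
        i -= k
        if i == 0:
            break
        blocks.append(("N", i - NUC_LEN + 1, NUC_LEN))
        i -= NUC_LEN
    blocks.reverse()
    path = StatePath(blocks)
    path.validate(n, F.tau_l)
    return path


def affinity(seq, nuc: NucleosomeModel = None, link: LinkerModel = None, *,
             em: Optional[Emissions] = None) -> np.ndarray:
    """Histone-binding affinity a_i: both-strand log-likelihood ratio
    (nucleosome vs linker) of the 147-bp window centered at i.

    Returns a length-n vector with NaN outside [74, n-73]; an empty vector
    when no window fits (n < 147).  No linker-length term enters: this is a
    pure emission contrast.
    """
    em = _get_em(seq, nuc, link, em)
    n = em.n
    if n < NUC_LEN:
        return np.zeros(0)
    out = np.full(n, np.nan)
    starts = np.arange(1, n - NUC_LEN + 2)
    link_ll = em.linker_segment_loglik(starts, starts + NUC_LEN - 1)
    out[73:n - 73] = em.en1[1:] - link_ll
    return out


def predict(seq, nuc: NucleosomeModel = None, link: LinkerModel = None,
            F: LinkerLengthDistribution = None, *,
            em: Optional[Emissions] = None) -> PredictionResult:
    """Full decoding of one record: occupancy, Viterbi map, affinity, log P(x)."""
    em = _get_em(seq, nuc, link, em)
    fb = forward_backward(None, F=F, em=em)
    return PredictionResult(
        occupancy=occupancy(fb),
        viterbi=viterbi(None, F=F, em=em),
        affinity=affinity(None, em=em),
        loglik=fb.loglik,
    )
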
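"""Iterative re-estimation of the linker-length distribution F_L.

Starting from an initial distribution (uniform by default), each iteration

1. runs forward/backward on every input sequence and accumulates the
   posterior expected number of linkers of each length k, E(n_k | x);
2. selects a Gaussian-kernel bandwidth by leave-one-out least-squares
   cross-validation over a grid, treating the expected counts as weighted
   observations on the integer grid 1..tau_L;
3. kernel-smooths the counts into the next distribution.

One iteration is the recommended production setting: it captures most of
the attainable improvement while staying robust to model misspecification
in atypical genomic regions; more iterations are available and typically
stabilize within four on well-specified inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .dhmm import (expected_linker_counts, expected_nucleosome_count,
                   forward_backward)
from .emission import Emissions, precompute
from .models import LinkerLengthDistribution, LinkerModel, NucleosomeModel


@dataclass
class KernelConfig:
    """Gaussian-kernel settings for the F_L update.

    ``bandwidth_grid`` is the candidate set for leave-one-out least-squares
    cross-validation (LSCV); the default covers 0.5-50 bp on a log scale.
    """

    bandwidth_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.5, 50.0, 20))

    def __post_init__(self) -> None:
        self.bandwidth_grid = np.asarray(self.bandwidth_grid, dtype=float)
        if self.bandwidth_grid.size == 0:
            raise ValueError("bandwidth grid must be non-empty")
        if np.any(self.bandwidth_grid <= 0):
            raise ValueError("bandwidths must be positive")


def kernel_smooth(counts: np.ndarray, h: float) -> LinkerLengthDistribution:
    """Gaussian-kernel smoothing of length counts on the grid 1..tau_L.

    F(k) is proportional to sum_j counts_j * phi((k - j) / h), renormalized
    over the grid (boundary mass is handled by the renormalization, not by
    reflection).  The Gaussian kernel guarantees full support.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if not np.any(counts > 0):
        raise ValueError("counts are all zero")
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    k = np.arange(1, len(counts) + 1, dtype=float)
    diff = (k[:, None] - k[None, :]) / h
    # phi evaluated row-wise; log-space for tiny bandwidths
    w = np.exp(-0.5 * diff * diff) @ counts
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("kernel smoothing produced no mass")
    return LinkerLengthDistribution(w / total)


def lscv_score(counts: np.ndarray, h: float) -> float:
    """Least-squares leave-one-out CV criterion for a weighted sample.

    The linker-length distribution lives on the integer grid 1..tau_L, so
    the criterion targets the grid pmf directly:

        LSCV(h) = sum_k fhat(k)^2 - (2/n) sum_j w_j fhat_{-j}(j)

    where fhat is the kernel-smoothed, grid-renormalized estimate and
    fhat_{-j} removes one observation at j.  This is the unbiased CV
    estimate of the squared grid error up to a constant; smaller is better.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 1:
        raise ValueError("effective sample size must exceed 1")
    k = np.arange(1, len(counts) + 1, dtype=float)
    diff = (k[:, None] - k[None, :]) / h
    phi = np.exp(-0.5 * diff * diff)
    col_norm = phi.sum(axis=0)  # grid renormalization per kernel center
    kern = phi / col_norm[None, :]
    fhat = kern @ (counts / n)
    # leave-one-out pmf evaluated at each support point j
    loo = (kern @ counts - np.diag(kern)) / (n - 1)
    return float(fhat @ fhat - 2.0 * (counts @ loo) / n)


def loocv_bandwidth(counts: np.ndarray,
                    config: Optional[KernelConfig] = None) -> float:
    """Grid bandwidth minimizing the LSCV criterion; ties take the smaller h.

    A degenerate input (a single support point) returns the smallest grid
    value with a warning.
    """
    config = config or KernelConfig()
    counts = np.asarray(counts, dtype=float)
    grid = np.sort(config.bandwidth_grid)
    if np.count_nonzero(counts > 0) < 2:
        warnings.warn("degenerate length sample (single support point); "
                      "using the smallest grid bandwidth")
        return float(grid[0])
    scores = np.array([lscv_score(counts, h) for h in grid])
    return float(grid[int(np.argmin(scores))])  # argmin takes first = smallest h


def update_linker_distribution(
        seqs: Sequence, nuc: NucleosomeModel, link: LinkerModel,
        F0: LinkerLengthDistribution, n_iter: int = 1,
        config: Optional[KernelConfig] = None,
        ems: Optional[Sequence[Emissions]] = None,
) -> Tuple[LinkerLengthDistribution, List[dict]]:
    """Run ``n_iter`` rounds of posterior-count + kernel-smoothing updates.

    ``seqs`` may be strings or SequenceRecords; ``ems`` may carry precomputed
    emission caches for them (one per sequence) to avoid recomputation.
    Returns the final distribution and per-iteration diagnostics (total
    log-likelihood under the pre-update F, posterior expected nucleosome
    count, and the selected bandwidth).
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    seqs = list(seqs)
    if not seqs:
        raise ValueError("need at least one sequence")
    config = config or KernelConfig()
    if ems is None:
        ems = [precompute(s.seq if hasattr(s, "seq") else s, nuc, link)
               for s in seqs]
    F = F0
    diagnostics: List[dict] = []
    for it in range(n_iter):
        counts = np.zeros(F.tau_l)
        loglik = 0.0
        nuc_count = 0.0
        for em in ems:
            fb = forward_backward(None, F=F, em=em)
            counts += expected_linker_counts(fb, F)
            loglik += fb.loglik
            nuc_count += expected_nucleosome_count(fb)
        h = loocv_bandwidth(counts, config)
        F = kernel_smooth(counts, h)
        diagnostics.append({
            "iteration": it + 1,
            "loglik": float(loglik),
            "expected_nucleosomes": float(nuc_count),
            "bandwidth": float(h),
        })
    return F, diagnostics
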
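"""Chromatin-genome simulation and the sensitivity/FDR evaluation protocol.

A simulated genome alternates linker and nucleosome blocks
(L N L N ... N L, so n_linkers = n_nucleosomes + 1): linker lengths are
drawn from a configurable law (Normal, Gamma, uniform, or an arbitrary
pmf), linker sequences from a homogeneous linker chain, and 147-bp
nucleosome sequences from a position-dependent nucleosome chain.  Ground
truth (nucleosome starts and linker lengths) is recorded.

Predictions are scored center-to-center: a true nucleosome is recovered
(sensitivity) if some predicted center lies within a tolerance (35 bp by
default) of its dyad; a predicted nucleosome is false (FDR) if no true
dyad lies within the tolerance.  No one-to-one pairing is imposed.

``run_table_experiment`` wraps the full loop - simulate, optionally
re-estimate the linker-length distribution for a given number of updates,
Viterbi-decode, score - over replicate genomes, reporting per-update means
and standard errors of the total prediction count, sensitivity, and FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .dhmm import viterbi
from .emission import precompute
from .linker_update import KernelConfig, update_linker_distribution
from .models import (NUC_LEN, LinkerLengthDistribution, LinkerModel,
                     NucleosomeModel)

DEFAULT_TOLERANCE = 35


# ---------------------------------------------------------------------------
# linker length laws


@dataclass(frozen=True)
class NormalLinkerLaw:
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, size)

    def cdf(self, x):
        if self.sigma == 0:
            return (np.asarray(x, dtype=float) >= self.mu).astype(float)
        return stats.norm.cdf(x, self.mu, self.sigma)


@dataclass(frozen=True)
class GammaLinkerLaw:
    """Gamma law with ``rate`` parameterization: mean = alpha / rate."""

    alpha: float
    rate: float

    def __post_init__(self):
        if self.alpha <= 0 or self.rate <= 0:
            raise ValueError("alpha and rate must be positive")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.gamma(self.alpha, 1.0 / self.rate, size)

    def cdf(self, x):
        return stats.gamma.cdf(x, self.alpha, scale=1.0 / self.rate)


@dataclass(frozen=True)
class UniformLinkerLaw:
    low: int
    high: int

    def __post_init__(self):
        if not (1 <= self.low <= self.high):
            raise ValueError("need 1 <= low <= high")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.integers(self.low, self.high + 1, size).astype(float)

    def cdf(self, x):
        x = np.floor(np.asarray(x, dtype=float) + 0.5)  # integer-valued law
        return np.clip((x - self.low + 1) / (self.high - self.low + 1), 0, 1)


@dataclass(frozen=True)
class PmfLinkerLaw:
    dist: LinkerLengthDistribution

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(np.arange(1, self.dist.tau_l + 1), size=size,
                          p=self.dist.pmf).astype(float)

    def cdf(self, x):
        cum = np.concatenate([[0.0], np.cumsum(self.dist.pmf)])
        idx = np.clip(np.floor(np.asarray(x, dtype=float) + 0.5), 0,
                      self.dist.tau_l).astype(int)
        return cum[idx]


LinkerLaw = Union[NormalLinkerLaw, GammaLinkerLaw, UniformLinkerLaw, PmfLinkerLaw]


def sample_linker_length(law: LinkerLaw, rng: np.random.Generator,
                         size: Optional[int] = None, tau_l: int = 500):
    """Draw linker lengths: continuous draw, round to nearest bp, clamp to [1, tau_L]."""
    m = 1 if size is None else size
    raw = np.rint(law.draw(rng, m)).astype(int)
    clamped = np.clip(raw, 1, tau_l)
    return int(clamped[0]) if size is None else clamped


def law_pmf(law: LinkerLaw, tau_l: int) -> LinkerLengthDistribution:
    """The integer-length pmf implied by round-then-clamp sampling."""
    half = np.arange(1, tau_l + 1) + 0.5    # k gets mass on (k-0.5, k+0.5]
    upper = law.cdf(half)
    pmf = np.diff(np.concatenate([[0.0], upper]))
    pmf[0] = upper[0]          # clamp: everything below 1.5 lands on k=1
    pmf[-1] = 1.0 - upper[-2] if tau_l > 1 else 1.0  # and the upper tail on tau_L
    return LinkerLengthDistribution(pmf / pmf.sum())


# ---------------------------------------------------------------------------
# genome simulation


@dataclass
class SimulatedGenome:
    """Sequence plus ground truth (1-based nucleosome starts, linker lengths)."""

    seq: str
    true_starts: np.ndarray
    linker_lengths: np.ndarray

    @property
    def true_centers(self) -> np.ndarray:
        return self.true_starts + 73

    def validate(self) -> None:
        if len(self.linker_lengths) != len(self.true_starts) + 1:
            raise ValueError("need n_nucleosomes + 1 linkers")
        expect = int(self.linker_lengths.sum()) + NUC_LEN * len(self.true_starts)
        if expect != len(self.seq):
            raise ValueError("block lengths inconsistent with sequence length")


def simulate_genome(nuc: NucleosomeModel, link: LinkerModel, law: LinkerLaw,
                    n_nucleosomes: int, seed, tau_l: int = 500) -> SimulatedGenome:
    """Alternate linker and nucleosome blocks; deterministic per seed."""
    if n_nucleosomes < 1:
        raise ValueError("need at least one nucleosome")
    rng = np.random.default_rng(seed)
    lens = sample_linker_length(law, rng, size=n_nucleosomes + 1, tau_l=tau_l)
    linkers = link.sample(lens, rng)
    cores = nuc.sample(rng, n_nucleosomes)
    parts = [linkers[0]]
    starts = np.empty(n_nucleosomes, dtype=int)
    pos = lens[0] + 1
    for i in range(n_nucleosomes):
        starts[i] = pos
        parts.append(cores[i])
        parts.append(linkers[i + 1])
        pos += NUC_LEN + lens[i + 1]
    g = SimulatedGenome(seq="".join(parts), true_starts=starts,
                        linker_lengths=np.asarray(lens))
    g.validate()
    return g


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    total_predicted: int
    sensitivity: float  # percent of true nucleosomes recovered
    fdr: float          # percent of predictions with no true dyad nearby


def _has_neighbor(query: np.ndarray, ref: np.ndarray, tol: int) -> np.ndarray:
    """For each query point, is some reference point within +-tol?"""
    if len(ref) == 0:
        return np.zeros(len(query), dtype=bool)
    ref = np.sort(ref)
    idx = np.searchsorted(ref, query)
    left = ref[np.clip(idx - 1, 0, len(ref) - 1)]
    right = ref[np.clip(idx, 0, len(ref) - 1)]
    return (np.abs(query - left) <= tol) | (np.abs(query - right) <= tol)


def evaluate_predictions(pred_centers, true_centers,
                         tolerance: int = DEFAULT_TOLERANCE) -> EvalReport:
    """Center-to-center scoring with the +-tolerance rule (no 1:1 pairing)."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pred = np.sort(np.asarray(pred_centers, dtype=float))
    true = np.sort(np.asarray(true_centers, dtype=float))
    if len(true) == 0:
        raise ValueError("need at least one true nucleosome")
    sens = 100.0 * _has_neighbor(true, pred, tolerance).mean()
    if len(pred) == 0:
        return EvalReport(total_predicted=0, sensitivity=float(sens), fdr=0.0)
    fdr = 100.0 * (~_has_neighbor(pred, true, tolerance)).mean()
    return EvalReport(total_predicted=len(pred), sensitivity=float(sens),
                      fdr=float(fdr))


# ---------------------------------------------------------------------------
# table experiments


@dataclass
class ExperimentConfig:
    """One simulation-table experiment (a row block of the result table).

    Genomes are simulated from ``nuc``/``link``; predictions may scan with a
    different profile (``scan_nuc``/``scan_link``), which is how the
    rescaled-versus-unscaled contrast is run.  ``updates`` lists the
    linker-update counts at which to evaluate; the initial distribution is
    uniform on 1..``f0_tau``.
    """

    nuc: NucleosomeModel
    link: LinkerModel
    law: LinkerLaw
    n_nucleosomes: int
    replicates: int
    updates: Sequence[int] = (0, 1)
    scan_nuc: Optional[NucleosomeModel] = None
    scan_link: Optional[LinkerModel] = None
    f0_tau: int = 200
    sim_tau: int = 500
    tolerance: int = DEFAULT_TOLERANCE
    seed: int = 0
    kernel: KernelConfig = field(default_factory=KernelConfig)


def run_table_experiment(cfg: ExperimentConfig):
    """Simulate replicates, decode at each update count, and tabulate.

    Returns ``(table, raw)``: a DataFrame with one row per update count
    (means and standard errors across replicates, in percent for sensitivity
    and FDR) and the per-replicate raw metric arrays keyed by update count.
    """
    updates = sorted(set(int(u) for u in cfg.updates))
    if any(u < 0 for u in updates):
        raise ValueError("update counts must be >= 0")
    scan_nuc = cfg.scan_nuc or cfg.nuc
    scan_link = cfg.scan_link or cfg.link
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    raw = {u: {"total": [], "sensitivity": [], "fdr": []} for u in updates}
    for rep_seed in seeds:
        g = simulate_genome(cfg.nuc, cfg.link, cfg.law, cfg.n_nucleosomes,
                            seed=rep_seed, tau_l=cfg.sim_tau)
        em = precompute(g.seq, scan_nuc, scan_link)
        F = LinkerLengthDistribution.uniform(cfg.f0_tau)
        for u in range(max(updates) + 1):
            if u in raw:
                path = viterbi(None, F=F, em=em)
                rep = evaluate_predictions(path.nucleosome_centers,
                                           g.true_centers, cfg.tolerance)
                raw[u]["total"].append(rep.total_predicted)
                raw[u]["sensitivity"].append(rep.sensitivity)
                raw[u]["fdr"].append(rep.fdr)
            if u < max(updates):
                F, _diag = update_linker_distribution(
                    [g.seq], scan_nuc, scan_link, F, n_iter=1,
                    config=cfg.kernel, ems=[em])
    rows = []
    for u in updates:
        row = {"update": u}
        for key in ("total", "sensitivity", "fdr"):
            vals = np.asarray(raw[u][key], dtype=float)
            row[f"{key}_mean"] = vals.mean()
            row[f"{key}_se"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                                if len(vals) > 1 else 0.0)
        rows.append(row)
    for u in updates:
        for key in raw[u]:
            raw[u][key] = np.asarray(raw[u][key], dtype=float)
    return pd.DataFrame(rows), raw
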
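"""Estimation of nucleosome and linker emission models from sequence sets.

Nucleosome chains are trained from center-aligned 147-bp sequences (e.g.
MNase-liberated mononucleosome reads trimmed to the crystallographic wrap).
Training symmetrizes the data with reverse complements so that the
both-strand likelihood used at prediction time matches the training
objective, and smooths the position-specific body tables with a 3-bp
moving average to stabilize the sparse higher-order counts.

Linker chains are trained from read-free regions by pooling transition
counts across positions and strands (the linker model is homogeneous).

Also here: the read-selection and read-free-region utilities that turn a
mapped read set into training material, and a fixture generator that
emulates center-aligned nucleosome reads and linker sequences drawn from
known models (for validation by parameter recovery).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .models import (NUC_LEN, LinkerModel, NucleosomeModel, encode, revcomp)

DEFAULT_PSEUDOCOUNT = 0.5  # keeps unseen 5-mers from scoring -inf
DEDUP_RADIUS = 58          # centers closer than this are "the same nucleosome"


@dataclass(frozen=True)
class MappedRead:
    """A read placed on a shared coordinate system (1-based, closed)."""

    seq: str
    start: int
    end: int
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


def select_nucleosome_reads(reads: Iterable[MappedRead],
                            radius: int = DEDUP_RADIUS) -> List[str]:
    """Length-filter, deduplicate, and center-trim mapped nucleosome reads.

    Keeps reads of length 146-149 bp; reads whose centers fall within
    ``radius`` bp of each other (single-linkage along the sorted centers) are
    treated as one nucleosome and only the highest-scoring read survives
    (ties: leftmost start, then lexicographically smallest sequence).  Each
    kept read is cut to exactly 147 bp about its midpoint: the extra base of
    a 148-mer and the odd extra base of a 149-mer come off the 3' end; a
    146-mer is padded with one 'N' at the 3' end (the N is ignored by the
    trainers).
    """
    cand = [r for r in reads if 146 <= r.length <= 149]
    if not cand:
        return []
    cand.sort(key=lambda r: r.center)
    groups: List[List[MappedRead]] = [[cand[0]]]
    for r in cand[1:]:
        if r.center - groups[-1][-1].center <= radius:
            groups[-1].append(r)
        else:
            groups.append([r])
    out = []
    for grp in groups:
        best = min(grp, key=lambda r: (-r.score, r.start, r.seq))
        out.append(_to_147(best.seq))
    return out


def _to_147(seq: str) -> str:
    n = len(seq)
    if n == 147:
        return seq
    if n == 148:
        return seq[:147]
    if n == 149:
        return seq[1:148]
    if n == 146:
        return seq + "N"
    raise ValueError(f"read length {n} outside 146-149")


def find_linker_regions(intervals: Sequence[Tuple[int, int]], genome_length: int,
                        min_len: int = 7, max_len: int = 500) -> List[Tuple[int, int]]:
    """Maximal read-free intervals of length ``min_len``..``max_len``.

    Intervals are 1-based closed on a single coordinate system; the returned
    regions are the zero-coverage gaps used as putative linker DNA.
    """
    cov = np.zeros(genome_length + 2, dtype=np.int64)
    for s, e in intervals:
        if s < 1 or e > genome_length or s > e:
            raise ValueError(f"interval ({s}, {e}) outside [1, {genome_length}]")
        cov[s] += 1
        cov[e + 1] -= 1
    covered = np.cumsum(cov[:genome_length + 1])[1:] > 0
    out = []
    pos = 1
    for free, run in _runs(~covered):
        if free and min_len <= run <= max_len:
            out.append((pos, pos + run - 1))
        pos += run
    return out


def _runs(mask: np.ndarray):
    if len(mask) == 0:
        return
    changes = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    edges = np.concatenate([[0], changes, [len(mask)]])
    for a, b in zip(edges[:-1], edges[1:]):
        yield bool(mask[a]), int(b - a)


# ---------------------------------------------------------------------------
# model training


def _encode_matrix(seqs: Sequence[str], symmetrize: bool) -> np.ndarray:
    if symmetrize:
        seqs = list(seqs) + [revcomp(s) for s in seqs]
    return np.stack([encode(s) for s in seqs])


def _normalize(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    tab = counts + pseudocount
    sums = tab.sum(axis=-1, keepdims=True)
    out = np.where(sums > 0, tab / np.where(sums > 0, sums, 1.0), 0.25)
    return out


def _count_conditionals(mat: np.ndarray, pos: int, h: int) -> np.ndarray:
    """Counts of (history, base) at column ``pos`` with history length ``h``.

    Rows whose outcome or history contains an ambiguous base are skipped.
    """
    counts = np.zeros((4 ** h, 4))
    base = mat[:, pos]
    valid = base < 4
    code = np.zeros(mat.shape[0], dtype=np.int64)
    for t in range(1, h + 1):
        prev = mat[:, pos - t]
        valid &= prev < 4
        code += np.where(prev < 4, prev, 0).astype(np.int64) * (4 ** (t - 1))
    np.add.at(counts, (code[valid], base[valid].astype(np.int64)), 1.0)
    return counts


def smooth_body_tables(body: np.ndarray) -> np.ndarray:
    """3-bp moving average of body-table probabilities along the position axis.

    Uniform 1/3 weights; the first and last body positions average the two
    available neighbors.  Averaging normalized distributions preserves
    normalization, and a renormalization guards against rounding drift.
    """
    padded = np.concatenate([body[:1], body, body[-1:]])
    # boundary duplication makes the edge mean equal the two-neighbor mean
    sm = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    sm[0] = (body[0] + body[1]) / 2.0
    sm[-1] = (body[-2] + body[-1]) / 2.0
    return sm / sm.sum(axis=-1, keepdims=True)


def train_nucleosome_model(aligned: Sequence[str], order: int = 4,
                           pseudocount: float = DEFAULT_PSEUDOCOUNT,
                           smooth: bool = True,
                           symmetrize: bool = True) -> NucleosomeModel:
    """Position-specific conditional fractions from center-aligned 147-mers.

    The training set is augmented with the reverse complement of every
    sequence (switchable), ``pseudocount`` is added to every cell, and the
    body tables (positions order+1..147) are smoothed with the 3-bp moving
    average before renormalization.
    """
    if order not in (1, 4):
        raise ValueError("order must be 1 or 4")
    if not aligned:
        raise ValueError("need at least one training sequence")
    for s in aligned:
        if len(s) != NUC_LEN:
            raise ValueError(f"aligned sequences must be {NUC_LEN} bp, got {len(s)}")
    mat = _encode_matrix(aligned, symmetrize)
    init = tuple(_normalize(_count_conditionals(mat, p, p), pseudocount)
                 for p in range(order))
    body_counts = np.stack([_count_conditionals(mat, p, order)
                            for p in range(order, NUC_LEN)])
    body = _normalize(body_counts, pseudocount)
    if smooth:
        body = smooth_body_tables(body)
    return NucleosomeModel(order=order, init=init, body=body)


def train_linker_model(linkers: Sequence[str], order: int = 4,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT,
                       symmetrize: bool = True) -> LinkerModel:
    """Homogeneous transition fractions pooled across linker sequences.

    Counts are pooled over all positions of all sequences and both strands;
    the stationary composition is the pooled base frequency.
    """
    if order not in (1, 4):
        raise ValueError("order must be 1 or 4")
    if not linkers:
        raise ValueError("need at least one linker sequence")
    if all(len(s) <= order for s in linkers):
        raise ValueError(
            f"no linker sequence longer than the chain order ({order})")
    seqs = list(linkers) + ([revcomp(s) for s in linkers] if symmetrize else [])
    enc = [encode(s) for s in seqs]
    allb = np.concatenate(enc)
    stat_counts = np.bincount(allb[allb < 4], minlength=4).astype(float)
    stationary = _normalize(stat_counts[None, :], 0.0)[0]
    cond = []
    for j in range(1, order + 1):
        counts = np.zeros((4 ** j, 4))
        for b in enc:
            if len(b) <= j:
                continue
            base = b[j:]
            valid = base < 4
            code = np.zeros(len(base), dtype=np.int64)
            for t in range(1, j + 1):
                prev = b[j - t:len(b) - t]
                valid &= prev < 4
                code += np.where(prev < 4, prev, 0).astype(np.int64) * (4 ** (t - 1))
            np.add.at(counts, (code[valid], base[valid].astype(np.int64)), 1.0)
        cond.append(_normalize(counts, pseudocount))
    return LinkerModel(order=order, stationary=stationary, cond=tuple(cond))


def generate_training_fixtures(truth_nuc: NucleosomeModel,
                               truth_link: LinkerModel,
                               n_reads: int, seed: int,
                               linker_length_range: Tuple[int, int] = (7, 500)):
    """Synthetic stand-in for a mapped mononucleosome read set.

    Draws ``n_reads`` center-aligned 147-bp sequences from ``truth_nuc`` and
    ``n_reads`` linker sequences with lengths uniform on
    ``linker_length_range`` from ``truth_link``.  Deterministic per seed.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    reads = truth_nuc.sample(rng, n_reads)
    lo, hi = linker_length_range
    lengths = rng.integers(lo, hi + 1, size=n_reads)
    linkers = truth_link.sample(lengths, rng)
    return reads, linkers
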
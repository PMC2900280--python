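"""Emission-model containers for the two-state nucleosome/linker duration HMM.

The chromatin model alternates a fixed-length nucleosome state (147 bp of DNA
wrapped around the histone octamer) with a variable-length linker state.  Each
state emits DNA through a Markov chain:

* the nucleosome chain is *position dependent*: the conditional distribution of
  the base at wrap position ``k`` (1..147) given the previous ``order`` bases
  changes with ``k``, which captures the ~10-bp rotational dinucleotide signal;
* the linker chain is *homogeneous*: one stationary composition plus one
  conditional table per history length up to ``order``.

Both states are always scored on both strands: the log-likelihood of a segment
is the sum of the Watson-strand log-likelihood and the log-likelihood of its
reverse complement under the same tables (position 1 of the reverse complement
aligns with model position 1).  This makes every score strand symmetric by
construction.

Supported chain orders are 1 and 4.  A linker length distribution ``F_L(k)``
over k = 1..tau_L completes the generative model; inference lives in
:mod:`nucdhmm.dhmm`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import yaml

NUC_LEN = 147
BASES = "ACGT"
LOG_QUARTER = math.log(0.25)
_NORM_TOL = 1e-9

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement; ambiguity codes map to their IUPAC complements."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA as int8: A,C,G,T -> 0..3, anything else -> 4 (ambiguous)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(idx: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[np.asarray(idx, dtype=np.intp)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# base composition


@dataclass(frozen=True)
class BaseComposition:
    """Genome-wide fractions of A/C/G/T (each in [0,1], summing to 1)."""

    freq_a: float
    freq_c: float
    freq_g: float
    freq_t: float

    def __post_init__(self) -> None:
        f = self.as_array()
        if np.any(f < -_NORM_TOL) or np.any(f > 1 + _NORM_TOL):
            raise ValueError("base fractions must lie in [0, 1]")
        if abs(float(f.sum()) - 1.0) > _NORM_TOL:
            raise ValueError("base fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.freq_a, self.freq_c, self.freq_g, self.freq_t])

    @property
    def at(self) -> float:
        return self.freq_a + self.freq_t

    @property
    def gc(self) -> float:
        return self.freq_c + self.freq_g

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls(0.25, 0.25, 0.25, 0.25)

    @classmethod
    def from_at(cls, at: float) -> "BaseComposition":
        """Symmetric composition (A=T, C=G) with the given A+T fraction."""
        return cls(at / 2, (1 - at) / 2, (1 - at) / 2, at / 2)


def base_composition(seq: str) -> BaseComposition:
    """Fractions of A/C/G/T in ``seq``; ambiguous bases are skipped."""
    b = encode(seq)
    counts = np.bincount(b[b < 4], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T base")
    counts /= total
    return BaseComposition(*counts.tolist())


# ---------------------------------------------------------------------------
# table helpers

def _check_table(tab: np.ndarray, what: str) -> None:
    if tab.shape[-1] != 4:
        raise ValueError(f"{what}: last axis must have size 4")
    if np.any(tab < -_NORM_TOL) or np.any(tab > 1 + _NORM_TOL):
        raise ValueError(f"{what}: probabilities must lie in [0, 1]")
    sums = tab.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > _NORM_TOL):
        raise ValueError(f"{what}: conditional distributions must sum to 1")


def history_to_code(hist: Sequence[int]) -> int:
    """History (oldest base first) -> row index; oldest is most significant."""
    code = 0
    for b in hist:
        code = code * 4 + int(b)
    return code


def code_to_history(code: int, h: int) -> str:
    out = []
    for _ in range(h):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _sample_rows(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one base per row of an (m, 4) probability matrix."""
    c = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0])
    return (u[:, None] > c).sum(axis=1).clip(0, 3).astype(np.int8)


# ---------------------------------------------------------------------------
# models


@dataclass
class NucleosomeModel:
    """Position-dependent Markov chain over the 147 positions of the wrap.

    ``init[j]`` (j = 0..order-1) holds the conditional table for position
    j+1 given a history of length j; ``body[k]`` holds the full-order table
    for position order+1+k.  Row index encodes the history with the oldest
    base most significant; columns are A, C, G, T.
    """

    order: int
    init: tuple
    body: np.ndarray
    length: int = NUC_LEN

    def __post_init__(self) -> None:
        self.init = tuple(np.asarray(t, dtype=float) for t in self.init)
        self.body = np.asarray(self.body, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.order not in (1, 4):
            raise ValueError("order must be 1 or 4")
        if self.length != NUC_LEN:
            raise ValueError(f"nucleosome length is fixed at {NUC_LEN}")
        if len(self.init) != self.order:
            raise ValueError("need one initial table per position 1..order")
        for j, tab in enumerate(self.init):
            if tab.shape != (4 ** j, 4):
                raise ValueError(f"init table {j} must have shape ({4**j}, 4)")
            _check_table(tab, f"nucleosome init table {j}")
        if self.body.shape != (NUC_LEN - self.order, 4 ** self.order, 4):
            raise ValueError("body tables must cover positions order+1..147")
        _check_table(self.body, "nucleosome body tables")

    def table_for_position(self, p: int) -> np.ndarray:
        """Conditional table at 0-based position ``p`` (history length min(p, order))."""
        return self.init[p] if p < self.order else self.body[p - self.order]

    def sample(self, rng: np.random.Generator, n: int = 1) -> list:
        """Draw ``n`` 147-bp nucleosome sequences."""
        out = np.empty((n, NUC_LEN), dtype=np.int8)
        codes = np.zeros(n, dtype=np.int64)
        for p in range(NUC_LEN):
            h = min(p, self.order)
            tab = self.table_for_position(p)
            out[:, p] = _sample_rows(tab[codes], rng)
            if p + 1 < NUC_LEN:
                hn = min(p + 1, self.order)
                if hn > h:
                    codes = codes * 4 + out[:, p]
                else:
                    codes = (codes % (4 ** (hn - 1))) * 4 + out[:, p]
        return [decode(row) for row in out]


@dataclass
class LinkerModel:
    """Homogeneous Markov chain for linker DNA.

    ``stationary`` is the base composition used when no history is available;
    ``cond[j-1]`` (j = 1..order) is the conditional table for history length j.
    """

    order: int
    stationary: np.ndarray
    cond: tuple

    def __post_init__(self) -> None:
        self.stationary = np.asarray(self.stationary, dtype=float)
        self.cond = tuple(np.asarray(t, dtype=float) for t in self.cond)
        self.validate()

    def validate(self) -> None:
        if self.order not in (1, 4):
            raise ValueError("order must be 1 or 4")
        if self.stationary.shape != (4,):
            raise ValueError("stationary composition must have shape (4,)")
        _check_table(self.stationary[None, :], "linker stationary composition")
        if len(self.cond) != self.order:
            raise ValueError("need one conditional table per history length 1..order")
        for j, tab in enumerate(self.cond, start=1):
            if tab.shape != (4 ** j, 4):
                raise ValueError(f"linker table for history {j} must be ({4**j}, 4)")
            _check_table(tab, f"linker conditional table (history {j})")

    def table_for_history(self, h: int) -> np.ndarray:
        return self.stationary[None, :] if h == 0 else self.cond[h - 1]

    def sample(self, lengths: Union[int, Sequence[int]], rng: np.random.Generator) -> list:
        """Draw linker sequences of the given lengths (batched)."""
        lens = np.atleast_1d(np.asarray(lengths, dtype=int))
        if np.any(lens < 1):
            raise ValueError("linker lengths must be >= 1")
        m, maxlen = len(lens), int(lens.max())
        out = np.empty((m, maxlen), dtype=np.int8)
        codes = np.zeros(m, dtype=np.int64)
        for p in range(maxlen):
            h = min(p, self.order)
            tab = self.table_for_history(h)
            rows = tab[codes if h else np.zeros(m, dtype=np.int64)]
            out[:, p] = _sample_rows(rows, rng)
            hn = min(p + 1, self.order)
            if hn > h:
                codes = codes * 4 + out[:, p]
            else:
                codes = (codes % (4 ** (hn - 1))) * 4 + out[:, p] if hn else codes
        return [decode(out[i, :lens[i]]) for i in range(m)]


@dataclass
class LinkerLengthDistribution:
    """Probability mass function of linker lengths, k = 1..tau_L."""

    pmf: np.ndarray

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.pmf.ndim != 1 or len(self.pmf) < 1:
            raise ValueError("pmf must be a non-empty vector")
        if np.any(self.pmf < 0):
            raise ValueError("pmf entries must be >= 0")
        if abs(float(self.pmf.sum()) - 1.0) > _NORM_TOL:
            raise ValueError("pmf must sum to 1")

    @property
    def tau_l(self) -> int:
        return len(self.pmf)

    def log_pmf(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.pmf)

    @classmethod
    def uniform(cls, tau_l: int) -> "LinkerLengthDistribution":
        return cls(np.full(tau_l, 1.0 / tau_l))


# ---------------------------------------------------------------------------
# likelihoods


def _strand_loglik_nuc(b: np.ndarray, model: NucleosomeModel) -> float:
    total = 0.0
    for p in range(NUC_LEN):
        h = min(p, model.order)
        if b[p] >= 4 or (h and np.any(b[p - h:p] >= 4)):
            total += LOG_QUARTER
            continue
        tab = model.table_for_position(p)
        pr = tab[history_to_code(b[p - h:p]), b[p]]
        if pr <= 0.0:
            return -math.inf
        total += math.log(pr)
    return total


def nucleosome_loglik(seq: str, model: NucleosomeModel) -> float:
    """Both-strand log-probability of a 147-bp window under the nucleosome chain.

    Returns ``log[P(seq) * P(revcomp(seq))]``; a zero-probability transition on
    either strand yields ``-inf`` (a sentinel for a forbidden window, not an
    error).  Ambiguous bases contribute ln(0.25) per strand.
    """
    if len(seq) != NUC_LEN:
        raise ValueError(f"nucleosome window must be {NUC_LEN} bp, got {len(seq)}")
    return (_strand_loglik_nuc(encode(seq), model)
            + _strand_loglik_nuc(encode(revcomp(seq)), model))


def _strand_loglik_link(b: np.ndarray, model: LinkerModel) -> float:
    total = 0.0
    for i in range(len(b)):
        h = min(i, model.order)
        if b[i] >= 4 or (h and np.any(b[i - h:i] >= 4)):
            total += LOG_QUARTER
            continue
        tab = model.table_for_history(h)
        pr = tab[history_to_code(b[i - h:i]) if h else 0, b[i]]
        if pr <= 0.0:
            return -math.inf
        total += math.log(pr)
    return total


def linker_loglik(seq: str, model: LinkerModel) -> float:
    """Both-strand log-probability of a linker segment of any length >= 1.

    Positions with less history than ``order`` (the first few bases of the
    segment) use the shorter-history tables; a single base is scored by the
    stationary composition on each strand.
    """
    if len(seq) == 0:
        raise ValueError("linker segment must be non-empty")
    return (_strand_loglik_link(encode(seq), model)
            + _strand_loglik_link(encode(revcomp(seq)), model))


# ---------------------------------------------------------------------------
# cross-species rescaling


def class_factors(source: BaseComposition, target: BaseComposition) -> np.ndarray:
    """Per-base scale factors; A/T share the A+T class ratio, G/C the G+C ratio."""
    if source.at <= 0 or source.gc <= 0:
        raise ValueError("source composition has an empty base class")
    f_at = target.at / source.at
    f_gc = target.gc / source.gc
    return np.array([f_at, f_gc, f_gc, f_at])


def _rescale_table(tab: np.ndarray, factors: np.ndarray) -> np.ndarray:
    scaled = tab * factors
    sums = scaled.sum(axis=-1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("rescaling zeroed out a conditional distribution")
    return scaled / sums


def rescale_model(model, source: BaseComposition, target: BaseComposition):
    """Port a model across species by base-composition class rescaling.

    Every conditional probability for outcome base b is multiplied by
    (target class fraction)/(source class fraction) of b's A/T or G/C class,
    then each conditional distribution is renormalized.  Works for both
    :class:`NucleosomeModel` and :class:`LinkerModel`; structure is unchanged.
    """
    factors = class_factors(source, target)
    if isinstance(model, NucleosomeModel):
        return NucleosomeModel(
            order=model.order,
            init=tuple(_rescale_table(t, factors) for t in model.init),
            body=_rescale_table(model.body, factors),
        )
    if isinstance(model, LinkerModel):
        return LinkerModel(
            order=model.order,
            stationary=_rescale_table(model.stationary[None, :], factors)[0],
            cond=tuple(_rescale_table(t, factors) for t in model.cond),
        )
    raise TypeError(f"cannot rescale object of type {type(model).__name__}")


# ---------------------------------------------------------------------------
# serialization

_FMT = "%.17g"  # 17 significant digits round-trip IEEE doubles exactly


def _iter_rows(model):
    if isinstance(model, NucleosomeModel):
        for p in range(NUC_LEN):
            h = min(p, model.order)
            tab = model.table_for_position(p)
            for code in range(4 ** h):
                hist = code_to_history(code, h) or "-"
                for b in range(4):
                    yield p + 1, hist, BASES[b], tab[code, b]
    else:
        for b in range(4):
            yield 0, "-", BASES[b], model.stationary[b]
        for j in range(1, model.order + 1):
            tab = model.cond[j - 1]
            for code in range(4 ** j):
                hist = code_to_history(code, j)
                for b in range(4):
                    yield 0, hist, BASES[b], tab[code, b]


def write_model(model, path) -> None:
    """Serialize a model; format chosen by extension (.tsv/.txt, .json, .yaml)."""
    path = Path(path)
    if path.suffix in (".json", ".yaml", ".yml"):
        doc = model_to_dict(model)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(doc, fh)
            else:
                yaml.safe_dump(doc, fh)
        return
    kind = "nucleosome" if isinstance(model, NucleosomeModel) else "linker"
    with open(path, "w") as fh:
        fh.write(f"#type\t{kind}\n#order\t{model.order}\n")
        fh.write(f"#length\t{NUC_LEN if kind == 'nucleosome' else 0}\n")
        for pos, hist, b, pr in _iter_rows(model):
            fh.write(f"{pos}\t{hist}\t{b}\t{_FMT % pr}\n")


def model_to_dict(model) -> dict:
    if isinstance(model, NucleosomeModel):
        return {
            "type": "nucleosome",
            "order": model.order,
            "length": NUC_LEN,
            "init": [t.tolist() for t in model.init],
            "body": model.body.tolist(),
        }
    return {
        "type": "linker",
        "order": model.order,
        "stationary": model.stationary.tolist(),
        "cond": [t.tolist() for t in model.cond],
    }


def model_from_dict(doc: dict):
    if doc["type"] == "nucleosome":
        return NucleosomeModel(order=doc["order"],
                               init=tuple(np.array(t) for t in doc["init"]),
                               body=np.array(doc["body"]))
    if doc["type"] == "linker":
        return LinkerModel(order=doc["order"],
                           stationary=np.array(doc["stationary"]),
                           cond=tuple(np.array(t) for t in doc["cond"]))
    raise ValueError(f"unknown model type {doc.get('type')!r}")


def read_model(path):
    """Load a model written by :func:`write_model`."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return model_from_dict(json.load(fh))
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            return model_from_dict(yaml.safe_load(fh))
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                meta[key] = val
                continue
            pos, hist, b, pr = line.split("\t")
            rows.append((int(pos), "" if hist == "-" else hist,
                         BASES.index(b), float(pr)))
    order = int(meta["order"])
    if meta["type"] == "nucleosome":
        init = [np.zeros((4 ** j, 4)) for j in range(order)]
        body = np.zeros((NUC_LEN - order, 4 ** order, 4))
        for pos, hist, b, pr in rows:
            p = pos - 1
            code = history_to_code([BASES.index(c) for c in hist])
            if p < order:
                init[p][code, b] = pr
            else:
                body[p - order, code, b] = pr
        return NucleosomeModel(order=order, init=tuple(init), body=body)
    if meta["type"] == "linker":
        stationary = np.zeros(4)
        cond = [np.zeros((4 ** j, 4)) for j in range(1, order + 1)]
        for _pos, hist, b, pr in rows:
            if not hist:
                stationary[b] = pr
            else:
                code = history_to_code([BASES.index(c) for c in hist])
                cond[len(hist) - 1][code, b] = pr
        return LinkerModel(order=order, stationary=stationary, cond=tuple(cond))
    raise ValueError(f"unknown model type {meta.get('type')!r}")


def write_linker_length_distribution(dist: LinkerLengthDistribution, path) -> None:
    """Two-column TSV: k, F(k)."""
    with open(path, "w") as fh:
        fh.write("k\tF\n")
        for k, p in enumerate(dist.pmf, start=1):
            fh.write(f"{k}\t{_FMT % p}\n")


def read_linker_length_distribution(path) -> LinkerLengthDistribution:
    pmf = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("k\t"):
            raise ValueError("expected header 'k\\tF'")
        for line in fh:
            if line.strip():
                _k, p = line.split("\t")
                pmf.append(float(p))
    return LinkerLengthDistribution(np.array(pmf))
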
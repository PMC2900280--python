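"""FASTA input, result writers, and the end-to-end prediction pipeline.

Per-record prediction output is a TSV with one row per position:

    Position  N/L  P-start  Occup  Affinity

``N/L`` is the Viterbi state (1 = nucleosome), ``P-start`` marks positions
where a Viterbi nucleosome begins, ``Occup`` is the posterior occupancy
(6 decimals), and ``Affinity`` the log-likelihood-ratio score (empty where
no full 147-bp window fits).  All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, TextIO, Tuple, Union

import numpy as np
from Bio import SeqIO

from .dhmm import PredictionResult, SequenceRecord, predict
from .emission import precompute
from .linker_update import KernelConfig, update_linker_distribution
from .models import (BaseComposition, LinkerLengthDistribution, LinkerModel,
                     NucleosomeModel, base_composition)
from . import species as species_mod


class FastaParseError(ValueError):
    """Raised with a line number when a FASTA file is malformed."""


def read_fasta(path) -> List[SequenceRecord]:
    """Parse a (possibly multi-record, wrapped) FASTA file.

    Sequences are uppercased; ambiguity codes are preserved for the
    downstream ambiguity policy; ids are the header token up to the first
    whitespace.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected '>' header, "
                    f"got {line.strip()[:30]!r}")
            break
        else:
            raise FastaParseError(f"{path}: line 0: empty FASTA file")
    records = [SequenceRecord(id=rec.id, seq=str(rec.seq).upper())
               for rec in SeqIO.parse(path, "fasta")]
    for i, rec in enumerate(records, start=1):
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {i} ({rec.id}) is empty")
    return records


def write_prediction_tsv(result: PredictionResult, out: Union[str, Path, TextIO],
                         header: bool = True) -> None:
    """Stream the per-position prediction table."""
    close = False
    if not hasattr(out, "write"):
        out = open(out, "w")
        close = True
    try:
        n = len(result.occupancy)
        z = result.viterbi.state_vector(n)
        starts = np.zeros(n, dtype=np.int8)
        starts[result.viterbi.nucleosome_starts - 1] = 1
        aff = result.affinity if len(result.affinity) == n else np.full(n, np.nan)
        if header:
            out.write("Position\tN/L\tP-start\tOccup\tAffinity\n")
        for i in range(n):
            a = "" if np.isnan(aff[i]) else f"{aff[i]:.6f}"
            out.write(f"{i + 1}\t{z[i]}\t{starts[i]}\t"
                      f"{result.occupancy[i]:.6f}\t{a}\n")
    finally:
        if close:
            out.close()


def write_occupancy_wig(result: PredictionResult, record_id: str,
                        out: Union[str, Path, TextIO]) -> None:
    """Fixed-step WIG track of the posterior occupancy."""
    close = False
    if not hasattr(out, "write"):
        out = open(out, "w")
        close = True
    try:
        out.write(f"fixedStep chrom={record_id} start=1 step=1\n")
        for v in result.occupancy:
            out.write(f"{v:.6f}\n")
    finally:
        if close:
            out.close()


def write_centers_bed(centers: Sequence[int], chrom: str,
                      out: Union[str, Path, TextIO]) -> None:
    """1-bp BED-like TSV of predicted centers (1-based inclusive coordinates)."""
    close = False
    if not hasattr(out, "write"):
        out = open(out, "w")
        close = True
    try:
        for c in centers:
            out.write(f"{chrom}\t{c}\t{c}\n")
    finally:
        if close:
            out.close()


def predict_records(
        records: Sequence[SequenceRecord],
        nuc: NucleosomeModel, link: LinkerModel,
        tau_l: int = 500,
        linker_updates: int = 1,
        rescale_to: Optional[BaseComposition] = None,
        kernel: Optional[KernelConfig] = None,
) -> Tuple[List[PredictionResult], LinkerLengthDistribution]:
    """End-to-end prediction for a batch of records.

    Optional base-composition rescaling of the profile, then the default
    single linker-length update (posterior counts pooled across records,
    uniform initialization on 1..tau_L), then per-record decoding.
    """
    if not records:
        raise ValueError("no records to predict")
    if rescale_to is not None:
        source = species_mod.YEAST_COMPOSITION
        from .models import rescale_model
        nuc = rescale_model(nuc, source, rescale_to)
        link = rescale_model(link, source, rescale_to)
    ems = [precompute(r.seq, nuc, link) for r in records]
    F = LinkerLengthDistribution.uniform(tau_l)
    if linker_updates > 0:
        F, _diag = update_linker_distribution(
            [r.seq for r in records], nuc, link, F,
            n_iter=linker_updates, config=kernel, ems=ems)
    return [predict(None, F=F, em=em) for em in ems], F
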
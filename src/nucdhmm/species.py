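"""Species registry, model selection by base composition, and bundled profiles.

The bundled emission profiles are *synthetic surrogates*: deterministic,
yeast-like constructions that reproduce the qualitative sequence features a
nucleosome model trained on real mononucleosome reads exhibits - linker DNA
richer in A/T than nucleosomal DNA (poly(dA:dT) tracts are disfavored by the
wrap) and an ~10-bp periodic W/S dinucleotide signal phased about the dyad.
They are intended for simulation studies, fixtures, and demonstrations, not
as substitutes for profiles trained on experimental data; user-trained
models can be loaded from file wherever a profile is accepted.

Model portability across species uses base-composition rescaling: the
registry stores one composition per species, predictions pick the species
with the closest A+T fraction, and the base profile is rescaled to it.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np

from .models import (NUC_LEN, BaseComposition, LinkerModel, NucleosomeModel,
                     rescale_model)

#: Base profile composition (budding yeast, A+T fraction 0.617).
YEAST_COMPOSITION = BaseComposition.from_at(0.617)

#: Species registry: name -> genome base composition.  The C. elegans and
#: maize entries pin the A+T fraction 0.645 and the G/C class factor 1.2
#: relative to yeast; human sits at an A/T class factor of 1.03.
SPECIES_COMPOSITIONS: Dict[str, BaseComposition] = {
    "saccharomyces_cerevisiae": YEAST_COMPOSITION,
    "caenorhabditis_elegans": BaseComposition.from_at(0.645),
    "homo_sapiens": BaseComposition.from_at(0.617 * 1.03),
    "zea_mays": BaseComposition.from_at(1.0 - 0.383 * 1.2),
}

# Surrogate-profile shape constants.  The dinucleotide period and the signal
# amplitudes are set so that simulated genomes scanned with the matching
# profile sit in the published operating regime of sequence-based nucleosome
# predictors (roughly 70-75% sensitivity at +-35 bp before any linker-length
# update); they are fixed, not tuned per experiment.
_PERIOD = 10.2
_NUC_AT = 0.576          # nucleosomal DNA is less A/T-rich than linker DNA
_LINK_AT = 0.66
_AMP = 0.05              # amplitude of the periodic composition signal
_DIN = 0.20              # extra periodic weight for WW/SS stacking
_STACK = 0.12            # homogeneous stacking preference in linker DNA
_ORDER2 = 0.06           # second-order taste that distinguishes order 4


def _phase(p: int) -> float:
    """Periodic signal at 0-based wrap position p, phased on the dyad (73)."""
    return math.cos(2.0 * math.pi * (p - 73) / _PERIOD)


def _is_w(b: int) -> bool:
    return b in (0, 3)  # A or T


def _nuc_conditional(p: int, hist: Tuple[int, ...]) -> np.ndarray:
    """Conditional base distribution at wrap position p given history."""
    ph = _phase(p)
    w = _NUC_AT / 2 + _AMP * ph / 2
    s = (1.0 - _NUC_AT) / 2 - _AMP * ph / 2
    probs = np.array([w, s, s, w])
    if hist:
        prev = hist[-1]
        boost = np.ones(4)
        for b in range(4):
            if _is_w(b) == _is_w(prev):
                boost[b] += _DIN * ph if _is_w(b) else -_DIN * ph
        if len(hist) >= 2:
            boost[hist[-2]] += _ORDER2
        probs = probs * np.clip(boost, 0.05, None)
    return probs / probs.sum()


def _link_conditional(hist: Tuple[int, ...]) -> np.ndarray:
    w = _LINK_AT / 2
    s = (1.0 - _LINK_AT) / 2
    probs = np.array([w, s, s, w])
    if hist:
        boost = np.ones(4)
        boost[hist[-1]] += _STACK
        if len(hist) >= 2:
            boost[hist[-2]] += _ORDER2
        probs = probs * boost
    return probs / probs.sum()


def _histories(h: int):
    for code in range(4 ** h):
        hist = []
        c = code
        for _ in range(h):
            hist.append(c % 4)
            c //= 4
        yield code, tuple(reversed(hist))


def surrogate_profile(order: int = 4) -> Tuple[NucleosomeModel, LinkerModel]:
    """Deterministic synthetic yeast-like nucleosome and linker chains."""
    if order not in (1, 4):
        raise ValueError("order must be 1 or 4")
    init = []
    for p in range(order):
        tab = np.empty((4 ** p, 4))
        for code, hist in _histories(p):
            tab[code] = _nuc_conditional(p, hist)
        init.append(tab)
    body = np.empty((NUC_LEN - order, 4 ** order, 4))
    for p in range(order, NUC_LEN):
        for code, hist in _histories(order):
            body[p - order, code] = _nuc_conditional(p, hist)
    nuc = NucleosomeModel(order=order, init=tuple(init), body=body)

    cond = []
    for j in range(1, order + 1):
        tab = np.empty((4 ** j, 4))
        for code, hist in _histories(j):
            tab[code] = _link_conditional(hist)
        cond.append(tab)
    stat = np.array([_LINK_AT / 2, (1 - _LINK_AT) / 2,
                     (1 - _LINK_AT) / 2, _LINK_AT / 2])
    link = LinkerModel(order=order, stationary=stat, cond=tuple(cond))
    return nuc, link


def select_species_model(input_comp: BaseComposition,
                         registry: Optional[Dict[str, BaseComposition]] = None
                         ) -> str:
    """Registry species with the closest A+T fraction (ties: alphabetical)."""
    registry = registry if registry is not None else SPECIES_COMPOSITIONS
    if not registry:
        raise ValueError("species registry is empty")
    return min(sorted(registry),
               key=lambda name: abs(input_comp.at - registry[name].at))


def models_for_species(species: str, order: int = 4,
                       registry: Optional[Dict[str, BaseComposition]] = None
                       ) -> Tuple[NucleosomeModel, LinkerModel]:
    """Surrogate profile rescaled from yeast to the species' composition."""
    registry = registry if registry is not None else SPECIES_COMPOSITIONS
    target = registry[species]
    nuc, link = surrogate_profile(order)
    return (rescale_model(nuc, YEAST_COMPOSITION, target),
            rescale_model(link, YEAST_COMPOSITION, target))
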
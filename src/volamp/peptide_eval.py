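"""Physicochemical evaluation of peptide sequence sets.

Global charge by Henderson-Hasselbalch summation over ionizable side chains
and both termini (Bjellqvist pKa scale by default), average molecular
weight, residue composition, and set-versus-set comparison.  External
AMP-probability predictors can be registered as plugins but are not shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_mw

from volamp.reservoir import STANDARD_AA

#: Bjellqvist pKa values, as used by common peptide-analysis packages.
BJELLQVIST_PKA = {
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
    "H": 5.98,
    "K": 10.0,
    "R": 12.0,
    "n_term": 7.5,
    "c_term": 3.55,
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class ChargeModel:
    """pKa table and pH for Henderson-Hasselbalch charge summation."""

    pka: dict[str, float] = field(default_factory=lambda: dict(BJELLQVIST_PKA))
    ph: float = 7.0

    def __post_init__(self) -> None:
        if not 0 < self.ph < 14:
            raise ValueError("pH must lie in (0, 14)")
        for name, value in self.pka.items():
            if not 0 < value < 14:
                raise ValueError(f"pKa for {name!r} out of range: {value}")


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, r in enumerate(sequence):
        if r not in STANDARD_AA:
            raise ValueError(f"unknown residue {r!r} at position {i}")


def global_charge(sequence: str, model: ChargeModel | None = None) -> float:
    """Net charge in elementary-charge units at the model's pH.

    Positive terms from K/R/H side chains and the N-terminus, negative terms
    from D/E/C/Y side chains and the C-terminus:
    ``+sum 1/(1+10^(pH-pKa)) - sum 1/(1+10^(pKa-pH))``.
    """
    _check_sequence(sequence)
    m = model if model is not None else ChargeModel()
    charge = 1.0 / (1.0 + 10.0 ** (m.ph - m.pka["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (m.pka["c_term"] - m.ph))
    for r in sequence:
        if r in _BASIC:
            charge += 1.0 / (1.0 + 10.0 ** (m.ph - m.pka[r]))
        elif r in _ACIDIC:
            charge -= 1.0 / (1.0 + 10.0 ** (m.pka[r] - m.ph))
    return charge


def molecular_weight(sequence: str, monoisotopic: bool = False) -> float:
    """Peptide molecular weight in daltons (average masses by default)."""
    _check_sequence(sequence)
    return _bio_mw(sequence, seq_type="protein", monoisotopic=monoisotopic)


def aa_distribution(sequences: list[str]) -> dict[str, float]:
    """Pooled residue frequencies over a sequence set, normalized to sum 1."""
    if not sequences:
        raise ValueError("need at least one sequence")
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        for r in seq:
            counts[r] = counts.get(r, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("sequences are all empty")
    return {r: c / total for r, c in sorted(counts.items())}


def l1_distance(dist_a: dict[str, float], dist_b: dict[str, float]) -> float:
    """L1 distance between two residue distributions (max 2 for disjoint)."""
    keys = set(dist_a) | set(dist_b)
    return float(sum(abs(dist_a.get(k, 0.0) - dist_b.get(k, 0.0)) for k in keys))


def compare_sets(
    set_a: list[str], set_b: list[str], model: ChargeModel | None = None
) -> dict:
    """Mean charge and weight per set, plus the L1 composition distance."""
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    m = model if model is not None else ChargeModel()
    report = {}
    for name, seqs in (("set_a", set_a), ("set_b", set_b)):
        report[name] = {
            "n": len(seqs),
            "mean_charge": float(np.mean([global_charge(s, m) for s in seqs])),
            "mean_molecular_weight": float(np.mean([molecular_weight(s) for s in seqs])),
        }
    report["distribution_l1"] = l1_distance(aa_distribution(set_a), aa_distribution(set_b))
    report["pka_table"] = dict(m.pka)
    report["ph"] = m.ph
    return report


_SCORERS: dict[str, Callable[[list[str]], list[float]]] = {}


def register_scorer(name: str, fn: Callable[[list[str]], list[float]]) -> None:
    """Register an external per-sequence probability scorer (plugin hook)."""
    _SCORERS[name] = fn


def score_sequences(name: str, sequences: list[str]) -> list[float]:
    """Apply a registered scorer; raises KeyError if none is registered."""
    if name not in _SCORERS:
        raise KeyError(f"no scorer registered under {name!r}")
    return _SCORERS[name](sequences)
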
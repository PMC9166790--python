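"""Synthetic AMP-like corpora and the in-text measurement fixtures.

The generator emulates the statistics of a cationic antimicrobial peptide
training set — short sequences (7-48 residues), composition exponentially
tilted toward the charged residues until the expected corpus mean global
charge hits a target (default +2.28), with an optional periodic hydrophobic
placement for crude amphipathicity.  No external data is ever fetched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from volamp.peptide_eval import ChargeModel, _ACIDIC, _BASIC
from volamp.reservoir import STANDARD_AA


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic corpus draw."""

    n_sequences: int = 500
    min_length: int = 7
    max_length: int = 48
    target_mean_charge: float = 2.28
    cationic_residues: tuple[str, ...] = ("K", "R")
    hydrophobic_residues: tuple[str, ...] = ("A", "F", "I", "L", "M", "V", "W")
    amphipathic_period: int | None = None
    seed: int = 0
    charge_model: ChargeModel = field(default_factory=ChargeModel)

    def __post_init__(self) -> None:
        if not 0 < self.min_length <= self.max_length:
            raise ValueError("need 0 < min_length <= max_length")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not np.isfinite(self.target_mean_charge):
            raise ValueError("target charge must be finite")
        if self.amphipathic_period is not None and self.amphipathic_period < 2:
            raise ValueError("amphipathic_period must be >= 2")


def _residue_charges(model: ChargeModel) -> np.ndarray:
    """Side-chain charge contribution of each standard residue at the model pH."""
    out = np.zeros(len(STANDARD_AA))
    for i, r in enumerate(STANDARD_AA):
        if r in _BASIC:
            out[i] = 1.0 / (1.0 + 10.0 ** (model.ph - model.pka[r]))
        elif r in _ACIDIC:
            out[i] = -1.0 / (1.0 + 10.0 ** (model.pka[r] - model.ph))
    return out


def _terminal_charge(model: ChargeModel) -> float:
    return 1.0 / (1.0 + 10.0 ** (model.ph - model.pka["n_term"])) - 1.0 / (
        1.0 + 10.0 ** (model.pka["c_term"] - model.ph)
    )


def tilted_composition(spec: CorpusSpec) -> np.ndarray:
    """Residue probabilities p_r ~ exp(beta * charge_r) matching the target.

    beta is solved so that the expected corpus mean global charge (termini
    plus expected length times expected per-residue charge, accounting for
    hydrophobic positions when amphipathicity is on) equals the target.
    """
    charges = _residue_charges(spec.charge_model)
    mean_len = (spec.min_length + spec.max_length) / 2.0
    hydro_frac = 0.0 if spec.amphipathic_period is None else 1.0 / spec.amphipathic_period
    need = (spec.target_mean_charge - _terminal_charge(spec.charge_model)) / (
        mean_len * (1.0 - hydro_frac)
    )
    if not charges.min() < need < charges.max():
        raise ValueError(
            f"target mean charge {spec.target_mean_charge} is infeasible for "
            f"lengths {spec.min_length}-{spec.max_length}"
        )

    def gap(beta: float) -> float:
        w = np.exp(beta * charges - (beta * charges).max())
        p = w / w.sum()
        return float(p @ charges) - need

    beta = brentq(gap, -200.0, 200.0)
    w = np.exp(beta * charges - (beta * charges).max())
    return w / w.sum()


def generate_corpus(spec: CorpusSpec) -> list[str]:
    """Draw a synthetic corpus; deterministic for a given spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    probs = tilted_composition(spec)
    residues = np.array(list(STANDARD_AA))
    hydro_idx = np.array([STANDARD_AA.index(r) for r in spec.hydrophobic_residues])
    hydro_probs = probs[hydro_idx] / probs[hydro_idx].sum()

    corpus = []
    for _ in range(spec.n_sequences):
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        idx = rng.choice(len(residues), size=length, p=probs)
        if spec.amphipathic_period is not None:
            for pos in range(0, length, spec.amphipathic_period):
                idx[pos] = hydro_idx[rng.choice(len(hydro_idx), p=hydro_probs)]
        corpus.append("".join(residues[idx]))
    return corpus


#: Magainin-2, the worked training example.
MAGAININ2 = "GIGKFLHSAKKFGKAFVGEIMNS"

#: The printed 20-step four-letter demonstration sequence.
DEMO_SEQUENCE = list("DDDCCBDCCDBADBACDCBA")

#: The seven demonstration binary input patterns.
BIT_PATTERNS = [
    [1, 1, 1, 1],
    [1, 1, 0, 1],
    [0, 0, 0, 1],
    [1, 1, 1, 0],
    [0, 0, 1, 0],
    [1, 0, 0, 0],
    [0, 0, 0, 0],
]


def fixtures() -> dict:
    """In-text measurement inputs used throughout the tests and demos."""
    return {
        "magainin2": MAGAININ2,
        "four_letter_sequence": list(DEMO_SEQUENCE),
        "bit_patterns": [list(p) for p in BIT_PATTERNS],
    }
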
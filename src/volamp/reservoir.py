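"""Multi-timescale memristive reservoir front-end for sequence learning.

Each residue of the input alphabet owns one cell in each of four device
groups driven with different duty cycles (W/I ratios), so the same symbol
stream is remembered over four different time windows.  A step potentiates
the current symbol's cell in every group, lets all cells decay at their
group rate, and reads out the full group x alphabet current vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from volamp.crossbar import DEFAULT_SLOT_TIME_SCALE
from volamp.device_model import DeviceParams, set_gain, tau_of_duty

END_CURSOR = "@"
#: The 20 standard amino acids, alphabetical one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet with the end cursor '@' as its last symbol."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.symbols.count(END_CURSOR) != 1 or self.symbols[-1] != END_CURSOR:
            raise ValueError("alphabet must contain '@' exactly once, in last position")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    @classmethod
    def standard(cls) -> "Alphabet":
        """20 standard amino acids plus the end cursor (size 21)."""
        return cls(tuple(STANDARD_AA) + (END_CURSOR,))

    @classmethod
    def from_corpus(cls, sequences: list[str]) -> "Alphabet":
        """Alphabet of the residues actually present in a corpus, plus '@'."""
        residues = sorted({r for seq in sequences for r in seq})
        if END_CURSOR in residues:
            raise ValueError("'@' is reserved for the end cursor")
        if not residues:
            raise ValueError("corpus contains no residues")
        return cls(tuple(residues) + (END_CURSOR,))

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"symbol {symbol!r} not in alphabet") from None


@dataclass(frozen=True)
class ReservoirConfig:
    """Drive parameters of the four duty-cycle groups."""

    duties: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
    set_amplitude: float = 4.0
    unit_slot: float = 100e-6
    read_amplitude: float = 1.5
    read_width: float = 100e-6
    slot_time_scale: float = DEFAULT_SLOT_TIME_SCALE
    device: DeviceParams = field(default_factory=DeviceParams)

    def __post_init__(self) -> None:
        if len(set(self.duties)) != len(self.duties):
            raise ValueError("duties must be distinct")
        if not all(0 < d < 1 for d in self.duties):
            raise ValueError("each duty must lie in (0, 1)")

    @property
    def n_groups(self) -> int:
        return len(self.duties)

    @property
    def step_interval(self) -> float:
        return (self.unit_slot + self.read_width) * self.slot_time_scale


def make_training_pairs(sequence: str, alphabet: Alphabet) -> list[tuple[str, str]]:
    """Next-symbol pairs for one sequence: target is the left-shifted string + '@'."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, r in enumerate(sequence):
        if r == END_CURSOR or r not in alphabet.symbols:
            raise ValueError(f"residue {r!r} at position {i} is not in the alphabet")
    targets = sequence[1:] + END_CURSOR
    return list(zip(sequence, targets))


class MemristorReservoir:
    """Stateful reservoir: |duties| groups x |alphabet| volatile cells.

    Features are raw read currents (amperes) concatenated group-major;
    multiplicative group gains (see :func:`fit_group_gains`) are applied when
    set, normalizing each group's calibration maximum to 1.
    """

    def __init__(self, alphabet: Alphabet, config: ReservoirConfig | None = None):
        self.alphabet = alphabet
        self.config = config if config is not None else ReservoirConfig()
        p = self.config.device
        # per-group drive constants, precomputed
        self._etas = np.array(
            [
                set_gain(p, self.config.set_amplitude, d * self.config.unit_slot)
                for d in self.config.duties
            ]
        )
        self._decays = np.array(
            [
                np.exp(-self.config.step_interval / tau_of_duty(d, p))
                for d in self.config.duties
            ]
        )
        self.group_gains: np.ndarray | None = None
        self.feature_scale: float = 1.0
        self.w = np.zeros((self.config.n_groups, alphabet.size))
        self.clock = 0.0

    @property
    def feature_size(self) -> int:
        return self.config.n_groups * self.alphabet.size

    def reset(self) -> None:
        """Return every cell to w = 0 and zero the clock."""
        self.w[:] = 0.0
        self.clock = 0.0

    def step(self, symbol: str) -> np.ndarray:
        """Process one symbol; returns the feature vector after the read stage."""
        j = self.alphabet.index(symbol)
        self.w[:, j] += self._etas * (1.0 - self.w[:, j])
        self.w *= self._decays[:, None]
        self.clock += self.config.step_interval
        return self.features()

    def features(self) -> np.ndarray:
        """Current group-major feature vector (gains applied if fitted)."""
        p = self.config.device
        currents = (
            p.g_off + self.w * (p.g_on - p.g_off)
        ) * self.config.read_amplitude
        if self.group_gains is not None:
            currents = currents * self.group_gains[:, None] * self.feature_scale
        return currents.ravel()

    def calibrate(self, raw_features: np.ndarray) -> None:
        """Freeze group gains (and unit normalization) from a calibration pass.

        After calibration each group's calibration maximum maps to 1, so
        features are unitless with overall maximum 1.
        """
        self.group_gains = fit_group_gains(
            raw_features, self.config.n_groups, self.alphabet.size
        )
        arr = np.atleast_2d(np.asarray(raw_features, dtype=float))
        self.feature_scale = 1.0 / arr.max()

    def encode_sequence(self, sequence: str) -> np.ndarray:
        """Reset, then stream a sequence; returns the (len x feature) matrix."""
        self.reset()
        return np.vstack([self.step(s) for s in sequence])


def fit_group_gains(
    features: np.ndarray, n_groups: int, alphabet_size: int
) -> np.ndarray:
    """Per-group amplification equalizing group maxima.

    ``features`` is any (n, groups*alphabet) matrix of raw currents from a
    calibration pass.  The gain of group g is (global max) / (max within g),
    so after amplification every group peaks at the same value; gains are
    invariant to a global rescaling of the features.
    """
    arr = np.atleast_2d(np.asarray(features, dtype=float))
    if arr.shape[1] != n_groups * alphabet_size:
        raise ValueError("feature width does not match groups x alphabet")
    per_group = arr.reshape(arr.shape[0], n_groups, alphabet_size)
    maxima = per_group.max(axis=(0, 2))
    if np.any(maxima <= 0) or np.isclose(arr.max(), arr.min(), rtol=1e-12, atol=0.0):
        raise ValueError("cannot fit gains on all-baseline features")
    return maxima.max() / maxima
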
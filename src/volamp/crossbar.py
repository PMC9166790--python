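"""Crossbar array of volatile memristors and the two pulse-train protocols.

Two encodings are supported: a 4-bit binary protocol (set pulse for "1",
ground slot for "0", read after every bit) and a duty-cycled symbol-sequence
protocol in which every alphabet symbol owns one cell and the duty cycle
(W/I ratio) of the set slot controls how fast history is forgotten.

The printed slot lengths (~100 us) are far below the decay constants
(15-40 ms); the measured traces nevertheless show strong order effects, so
the effective inter-step decay interval is ``(slot + read) * slot_time_scale``
with a default scale chosen to reproduce the printed recency/frequency
orderings.  This is a modeling choice, not a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from volamp.device_model import (
    DeviceParams,
    DeviceState,
    PulseSpec,
    apply_set_pulse,
    decay,
    read_current,
    sample_device,
    set_gain,
)

#: Default multiplier from electrical slot time to effective decay interval.
DEFAULT_SLOT_TIME_SCALE = 12.75


@dataclass(frozen=True)
class BitProtocol:
    """Binary protocol: 4.3 V / 50 us set, 100 us ground slot, 1.5 V / 200 us read."""

    set_pulse: PulseSpec = PulseSpec(4.3, 50e-6, "set")
    zero_slot_width: float = 100e-6
    read_pulse: PulseSpec = PulseSpec(1.5, 200e-6, "read")
    slot_time_scale: float = DEFAULT_SLOT_TIME_SCALE

    @property
    def step_interval(self) -> float:
        """Effective decay time elapsed per bit step."""
        return (self.zero_slot_width + self.read_pulse.width) * self.slot_time_scale


@dataclass(frozen=True)
class SequenceProtocol:
    """Symbol protocol: 100 us unit slot, duty-cycled 4 V set, 1.5 V / 100 us read."""

    unit_slot: float = 100e-6
    set_amplitude: float = 4.0
    duty: float = 0.5
    read_pulse: PulseSpec = PulseSpec(1.5, 100e-6, "read")
    slot_time_scale: float = DEFAULT_SLOT_TIME_SCALE

    def __post_init__(self) -> None:
        if not 0 < self.duty < 1:
            raise ValueError("duty must lie in (0, 1)")

    @property
    def set_pulse(self) -> PulseSpec:
        """The elevated portion of the unit slot."""
        return PulseSpec(self.set_amplitude, self.duty * self.unit_slot, "set")

    @property
    def step_interval(self) -> float:
        """Effective decay time elapsed per symbol step."""
        return (self.unit_slot + self.read_pulse.width) * self.slot_time_scale


class CrossbarArray:
    """Grid of volatile memristor cells with a symbol-to-cell assignment.

    Only the mapped cells carry state; the rest of the physical grid is
    inert.  Reads are idealized as sneak-path free (self-rectified), so
    reading one cell never perturbs another.
    """

    def __init__(
        self,
        symbols: list[str],
        n_rows: int = 20,
        n_cols: int = 20,
        params: DeviceParams | None = None,
        variation_seed: int | None = None,
    ):
        if len(set(symbols)) != len(symbols):
            raise ValueError("symbols must be unique")
        if len(symbols) > n_cols:
            raise ValueError("more symbols than columns")
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.symbols = list(symbols)
        base = params if params is not None else DeviceParams()
        if variation_seed is None:
            self.params = {s: base for s in symbols}
        else:
            self.params = {
                s: sample_device(base, variation_seed + i)
                for i, s in enumerate(symbols)
            }
        self.states = {s: DeviceState() for s in symbols}

    def reset(self) -> None:
        """Return every cell to the fresh state (w = 0, clock zeroed)."""
        self.states = {s: DeviceState() for s in self.symbols}

    def _read_all(self, v_read: float) -> np.ndarray:
        return np.array(
            [read_current(self.states[s], v_read, self.params[s]) for s in self.symbols]
        )


def run_bit_sequence(
    array: CrossbarArray, bits: list[int], protocol: BitProtocol | None = None
) -> list[float]:
    """Feed a binary pattern to every cell of the array; one read per bit.

    A "1" applies the set pulse, a "0" holds ground for the zero slot; all
    cells then decay over the scaled step interval before the read.  Returns
    the per-step read current of the first cell (all cells see the same
    pattern and respond identically unless variation-sampled).
    """
    if not bits:
        raise ValueError("bits must be non-empty")
    proto = protocol if protocol is not None else BitProtocol()
    currents = []
    for b in bits:
        if b not in (0, 1):
            raise ValueError(f"bits must be 0 or 1, got {b!r}")
        for s in array.symbols:
            if b == 1:
                array.states[s] = apply_set_pulse(
                    array.states[s], proto.set_pulse, array.params[s]
                )
            array.states[s] = decay(
                array.states[s], proto.step_interval, array.params[s]
            )
        currents.append(
            read_current(
                array.states[array.symbols[0]],
                proto.read_pulse.amplitude,
                array.params[array.symbols[0]],
            )
        )
    return currents


def run_symbol_sequence(
    array: CrossbarArray, symbols: list[str], protocol: SequenceProtocol
) -> np.ndarray:
    """Stream a symbol sequence through the array; returns (step x cell) currents.

    Per step the current symbol's cell receives one duty-cycled set slot,
    every cell decays with the duty-controlled time constant over the scaled
    step interval, and all cells are read.
    """
    for sym in symbols:
        if sym not in array.states:
            raise KeyError(f"symbol {sym!r} is not mapped to any cell")
    rows = []
    for sym in symbols:
        st = array.states[sym]
        gain = set_gain(array.params[sym], protocol.set_amplitude, protocol.set_pulse.width)
        array.states[sym] = apply_set_pulse(
            st, protocol.set_pulse, array.params[sym], gain=gain
        )
        for s in array.symbols:
            array.states[s] = decay(
                array.states[s],
                protocol.step_interval,
                array.params[s],
                duty=protocol.duty,
            )
        rows.append(array._read_all(protocol.read_pulse.amplitude))
    return np.vstack(rows)


def final_state_vector(array: CrossbarArray) -> np.ndarray:
    """Conductance of every mapped cell in alphabet order.

    On a fresh array every entry is the ``g_off`` baseline; after a protocol
    run it equals the final read-current row divided by the read voltage.
    """
    return np.array(
        [array.states[s].conductance(array.params[s]) for s in array.symbols]
    )
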
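"""Autoregressive sequence generation from a trained reservoir + readout.

A seed residue is streamed through the reservoir; the readout's softmax
output is sampled (temperature 1) for the next residue, which is fed back,
until the end cursor is drawn or a length cap is hit.  Exact duplicates of
training sequences are discarded from generation sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from volamp.readout import ReadoutNet
from volamp.reservoir import END_CURSOR, MemristorReservoir

DEFAULT_MAX_LEN = 60


@dataclass(frozen=True)
class GenerationRun:
    """One generation episode: seed, produced sequence, and stop condition."""

    seed: str
    sequence: str
    stop_reason: str  # "end_cursor" or "max_len"


def generate_one(
    net: ReadoutNet,
    reservoir: MemristorReservoir,
    seed: str,
    rng: np.random.Generator,
    max_len: int = DEFAULT_MAX_LEN,
    greedy: bool = False,
) -> GenerationRun:
    """Generate one sequence starting from ``seed``.

    The reservoir is reset first.  ``greedy=True`` takes the argmax instead
    of sampling (used for deterministic sanity checks).
    """
    if seed == END_CURSOR:
        raise ValueError("the end cursor cannot be used as a seed")
    reservoir.alphabet.index(seed)  # raises on unknown seed
    reservoir.reset()
    sequence = seed
    symbol = seed
    while len(sequence) < max_len:
        probs = net.forward(reservoir.step(symbol))
        if greedy:
            idx = int(np.argmax(probs))
        else:
            idx = int(rng.choice(len(probs), p=probs))
        nxt = reservoir.alphabet.symbols[idx]
        if nxt == END_CURSOR:
            return GenerationRun(seed=seed, sequence=sequence, stop_reason="end_cursor")
        sequence += nxt
        symbol = nxt
    return GenerationRun(seed=seed, sequence=sequence, stop_reason="max_len")


def generate_set(
    net: ReadoutNet,
    reservoir: MemristorReservoir,
    seeds: list[str],
    n: int,
    training_corpus: list[str],
    rng: np.random.Generator,
    max_len: int = DEFAULT_MAX_LEN,
    attempt_cap: int | None = None,
) -> list[GenerationRun]:
    """Generate until ``n`` sequences not present in the training corpus.

    Seeds are cycled in order.  If the attempt cap (default 10 n) is reached
    first, the partial set is returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not seeds:
        raise ValueError("seeds must be non-empty")
    cap = attempt_cap if attempt_cap is not None else 10 * n
    known = set(training_corpus)
    retained: list[GenerationRun] = []
    attempts = 0
    while len(retained) < n and attempts < cap:
        seed = seeds[attempts % len(seeds)]
        run = generate_one(net, reservoir, seed, rng, max_len=max_len)
        attempts += 1
        if run.sequence not in known:
            retained.append(run)
    if len(retained) < n:
        warnings.warn(
            f"attempt cap {cap} reached with only {len(retained)}/{n} novel sequences"
        )
    return retained
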
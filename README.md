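# volamp

Simulation toolkit for computing with **volatile (short-term memory)
memristors**: a phenomenological device model, a leaky-integrate-and-fire
(LIF) neuron circuit, crossbar pulse-train protocols, and a multi-timescale
memristive **reservoir** whose softmax readout learns and generates
antimicrobial-peptide (AMP)-like sequences. A synthetic corpus generator and
peptide physicochemistry utilities make the whole pipeline runnable offline.

## What is modeled

- **`device_model`** — one volatile memristor: saturating pulse potentiation
  (`w += eta (1 - w)`, calibrated so 16 set pulses at 4.5 V / 100 µs move
  55 nS → 1200 nS), exponential self-decay (τ = 40 ms at reference,
  Arrhenius temperature law with E_A = 0.21 eV), rectified non-perturbing
  reads (ratio 10⁴), device-to-device variation sampling (CV 3.87 %), plus
  decay-constant and activation-energy fitters.
- **`lif_neuron`** — series resistor + parallel capacitor + memristor soma.
  Exact piecewise-exponential integration; threshold calibrated once from the
  printed resistor-sweep/frequency experiments (47 kΩ → fires on pulse 3,
  94 kΩ → 6, 23.5 kΩ → 2, 1600 Hz → never).
- **`crossbar`** — arrays of cells with two protocols: 4-bit binary
  (4.3 V / 50 µs set, 1.5 V / 200 µs read) and duty-cycled symbol sequences
  (100 µs unit slot, 4 V set, duty = W/I ratio controlling the decay
  constant, 15–40 ms).
- **`reservoir`** — four duty-cycle groups (5/95 … 20/80) over a residue
  alphabet; each step potentiates one cell per group, everything decays, and
  the group×alphabet read-current vector (80-dim in the reduced-alphabet
  mode) is the feature, with per-group gain equalization.
- **`readout`** — 80×500×20-style MLP (ReLU hidden, softmax out; 50,520
  parameters in reference mode), trained online with next-residue
  cross-entropy (Adam by default, 50 epochs).
- **`generator`** — autoregressive sampling from a seed residue until the
  end cursor `@`; exact duplicates of training sequences are discarded.
- **`peptide_eval`** — Henderson–Hasselbalch global charge (Bjellqvist pKa),
  molecular weight, residue distributions, set comparison, plugin hook for
  external AMP-probability scorers.
- **`synthetic_data`** — AMP-like corpora (lengths 7–48, composition tilted
  to a target mean charge of +2.28) and the in-text fixtures (magainin-2,
  the four-letter demo sequence, the seven bit patterns).

## CLI

```sh
volamp device --pulses 16 --out decay.csv
volamp neuron --r-kohm 47 --c-nf 10 --pulses 10
volamp crossbar bits --pattern 1101
volamp crossbar seq --file seq.txt --duty 0.85
volamp synth --n 500 --seed 1 --out synth.fasta
volamp train --corpus synth.fasta --epochs 50 --seed 7 --out model.ckpt
volamp generate --model model.ckpt --corpus synth.fasta --n 100 --seed 13 --out gen.fasta
volamp evaluate --generated gen.fasta --reference synth.fasta
volamp pipeline --seed 1 --out run_dir      # synth -> train -> generate -> evaluate
volamp fixtures --out fixtures_dir
```

All artifacts are plain text (FASTA, CSV, JSON; checkpoints are JSON with
base64-encoded weight arrays).

## Modeling notes

The electrical slot times (~100 µs) are far shorter than the decay constants
(15–40 ms), yet the reference measurements show strong order effects within
20-step sequences; the simulator therefore scales the effective inter-step
decay interval by `slot_time_scale` (default 12.75, i.e. ~2.55 ms per step).
The potentiation law, the duty→τ map, and the LIF firing threshold are
calibrated to the printed anchor points; they are modeling choices, not
measured device physics. See module docstrings for details.
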
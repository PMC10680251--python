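"""Synthetic 6mA-style benchmark data.

Real 6mA benchmarks are fixed-length windows (41 nt) centred on a candidate
methylation adenine, where the two classes differ in position-specific
flanking composition.  This module emulates exactly that shape with
position weight matrices (PWMs): each class draws its sequences
position-independently from its own PWM, with the centre position emitting
A with probability 1 in *both* classes (so the classes can only be told
apart by their flanks, as in the real task).

It deliberately does not model dinucleotide correlations or the base
composition of any particular genome — it exists so every pipeline stage is
exercisable without downloads, not to mimic Rosaceae/Rice/Arabidopsis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .sequence_io import DnaSequence, LabeledDataset, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PwmSpec:
    """Per-position emission probabilities over A, C, G, T.

    ``center_index`` is 1-based; that position emits A with probability 1.
    """

    probs: np.ndarray  # (length, 4)
    center_index: int

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ConfigurationError("PWM must be a (length, 4) matrix")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("each PWM row must sum to 1")
        c = self.center_index - 1
        if not (0 <= c < probs.shape[0]):
            raise ConfigurationError(f"center index {self.center_index} out of range")
        if probs[c, 0] != 1.0:
            raise ConfigurationError("center position must emit A with probability 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]


def make_pwm(length: int = 41, signal_strength: float = 0.0, seed: int = 0) -> PwmSpec:
    """A PWM with uniform background blended toward per-position preferences.

    Each non-centre position gets a seeded random preferred base; its
    distribution is ``(1-s)·uniform + s·indicator(preferred)`` with
    ``s = signal_strength``.  Strength 0 is uniform everywhere except the
    fixed-A centre; strength 1 is deterministic.  Length must be odd so a
    centre exists (centre = (length+1)/2, 1-based).
    """
    if length % 2 == 0:
        raise ConfigurationError(f"length {length} must be odd (a centre is needed)")
    if not 0.0 <= signal_strength <= 1.0:
        raise ConfigurationError(f"signal strength {signal_strength} outside [0, 1]")
    rng = np.random.default_rng(seed)
    preferred = rng.integers(0, 4, size=length)
    probs = np.full((length, 4), 0.25 * (1.0 - signal_strength))
    probs[np.arange(length), preferred] += signal_strength
    center = length // 2
    probs[center] = [1.0, 0.0, 0.0, 0.0]
    return PwmSpec(probs, center_index=center + 1)


def generate_dataset(
    n_pos: int,
    n_neg: int,
    pwm_pos: PwmSpec,
    pwm_neg: PwmSpec,
    seed: int = 0,
) -> LabeledDataset:
    """Sample a labeled dataset: positives from ``pwm_pos``, negatives from
    ``pwm_neg`` (position-independent draws).  Reproducible given ``seed``.
    """
    if pwm_pos.length != pwm_neg.length:
        raise ConfigurationError(
            f"PWM lengths differ: {pwm_pos.length} vs {pwm_neg.length}"
        )
    if n_pos < 1 or n_neg < 1:
        raise ConfigurationError("both class counts must be >= 1")
    rng = np.random.default_rng(seed)
    sequences: list[DnaSequence] = []
    for prefix, n, pwm in (("pos", n_pos, pwm_pos), ("neg", n_neg, pwm_neg)):
        # vectorised per-position inverse-CDF sampling
        cum = np.cumsum(pwm.probs, axis=1)
        u = rng.random((n, pwm.length))
        idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
        for i in range(n):
            sequences.append(
                DnaSequence(f"{prefix}_{i + 1}", "".join(_BASES[idx[i]]))
            )
    labels = np.concatenate(
        [np.ones(n_pos, dtype=np.int64), np.zeros(n_neg, dtype=np.int64)]
    )
    return LabeledDataset(sequences, labels, pwm_pos.length)


def write_fasta_pair(
    dataset: LabeledDataset, pos_path: str | Path, neg_path: str | Path
) -> None:
    """Write a labeled dataset back as the two-file FASTA convention."""
    pos = [s for s, y in zip(dataset.sequences, dataset.labels) if y == 1]
    neg = [s for s, y in zip(dataset.sequences, dataset.labels) if y == 0]
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
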
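"""Sequence representations for 6mA site prediction.

Seven encoders map a fixed-length DNA window to a real feature vector:

===========  =============================================  length (L=41)
one-hot      4-bit indicator per position                   164
NCP          3 chemical-property bits per position          123
EIIP         electron-ion interaction pseudopotential       41
ANF          accumulated (prefix) nucleotide frequency      41
ENAC         per-sliding-window base composition (S=5)      148
NAC          whole-sequence base composition                4
Kmer         overlapping k-mer frequencies (k=3)            64
===========  =============================================  =============

All positional encoders use the fixed base order A, C, G, T.  Feature names
follow the ``<prefix>_<i>`` convention with a 1-based index restarting in
each encoder block (e.g. ``one-hot_96``, ``EIIP_19``), so a flat one-hot
index *j* refers to position ``ceil(j/4)`` and base ``(j-1) mod 4``.

Residues outside A/C/G/T (present only under the opt-in ``mask`` alphabet
policy) contribute zeros to positional encoders and are excluded from
composition counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .sequence_io import DnaSequence, LabeledDataset

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# EIIP pseudopotentials, indexed A, C, G, T (stored exactly as 4-decimal values).
_EIIP = np.array([0.1260, 0.1340, 0.0806, 0.1335])

# NCP rows indexed A, C, G, T: (ring: purine, group: amino, H-bond: weak).
_NCP = np.array(
    [
        [1, 1, 1],  # A
        [0, 1, 0],  # C
        [1, 0, 0],  # G
        [0, 0, 1],  # T
    ],
    dtype=float,
)


def seq_to_indices(seq: "DnaSequence | str") -> np.ndarray:
    """Map residues to integer codes A=0, C=1, G=2, T=3; unknown = -1."""
    residues = seq.residues if isinstance(seq, DnaSequence) else seq.upper()
    return np.fromiter(
        (_BASE_INDEX.get(ch, -1) for ch in residues), dtype=np.int64, count=len(residues)
    )


def encode_onehot(seq: "DnaSequence | str") -> np.ndarray:
    """Position-major one-hot code: A=(1,0,0,0) ... T=(0,0,0,1); length 4L."""
    idx = seq_to_indices(seq)
    out = np.zeros((idx.size, 4))
    valid = idx >= 0
    out[np.nonzero(valid)[0], idx[valid]] = 1.0
    return out.ravel()


def encode_eiip(seq: "DnaSequence | str") -> np.ndarray:
    """Per-residue EIIP scalar (A 0.1260, C 0.1340, G 0.0806, T 0.1335); length L."""
    idx = seq_to_indices(seq)
    out = np.zeros(idx.size)
    valid = idx >= 0
    out[valid] = _EIIP[idx[valid]]
    return out


def encode_ncp(seq: "DnaSequence | str") -> np.ndarray:
    """Position-major nucleotide chemical property triplets; length 3L.

    Per residue: (purine ring, amino group, weak hydrogen bond), i.e.
    A=(1,1,1), C=(0,1,0), G=(1,0,0), T=(0,0,1).
    """
    idx = seq_to_indices(seq)
    out = np.zeros((idx.size, 3))
    valid = idx >= 0
    out[valid] = _NCP[idx[valid]]
    return out.ravel()


def encode_enac(seq: "DnaSequence | str", window_size: int = 5) -> np.ndarray:
    """Sliding-window base composition, 5'→3', step 1; length 4(L−S+1).

    Each length-S window contributes its (A, C, G, T) counts divided by S.
    """
    idx = seq_to_indices(seq)
    L, S = idx.size, window_size
    if S < 1 or S > L:
        raise ConfigurationError(f"ENAC window size {S} invalid for length {L}")
    onehot = np.zeros((L, 4))
    valid = idx >= 0
    onehot[np.nonzero(valid)[0], idx[valid]] = 1.0
    csum = np.vstack([np.zeros(4), np.cumsum(onehot, axis=0)])
    windows = (csum[S:] - csum[:-S]) / S  # (L-S+1, 4)
    return windows.ravel()


def encode_anf(seq: "DnaSequence | str") -> np.ndarray:
    """Accumulated nucleotide frequency; length L.

    Position i (1-based) maps to the relative frequency of its own residue
    within the prefix 1..i, so the first element is always 1.
    """
    residues = seq.residues if isinstance(seq, DnaSequence) else seq.upper()
    counts: dict[str, int] = {}
    out = np.empty(len(residues))
    for i, ch in enumerate(residues, start=1):
        counts[ch] = counts.get(ch, 0) + 1
        out[i - 1] = counts[ch] / i
    return out


def encode_nac(seq: "DnaSequence | str") -> np.ndarray:
    """Whole-sequence base composition (freq_A, freq_C, freq_G, freq_T)."""
    idx = seq_to_indices(seq)
    counts = np.bincount(idx[idx >= 0], minlength=4).astype(float)
    return counts / idx.size


def encode_kmer(seq: "DnaSequence | str", k: int = 3) -> np.ndarray:
    """Overlapping k-mer frequencies in lexicographic A<C<G<T order; length 4^k.

    Counts are divided by the number of windows, L−k+1.  Windows containing
    a masked residue are skipped (their mass is simply absent).
    """
    idx = seq_to_indices(seq)
    L = idx.size
    if k < 1 or k > L:
        raise ConfigurationError(f"k-mer size {k} invalid for length {L}")
    n_windows = L - k + 1
    out = np.zeros(4**k)
    powers = 4 ** np.arange(k - 1, -1, -1)
    for start in range(n_windows):
        window = idx[start : start + k]
        if np.any(window < 0):
            continue
        out[int(window @ powers)] += 1.0
    return out / n_windows


@dataclass(frozen=True)
class EncoderSpec:
    """Selects one encoder, with its applicable parameters.

    ``window_size`` applies only to ``enac`` (default 5); ``k`` only to
    ``kmer`` (default 3).
    """

    name: str
    window_size: int = 5
    k: int = 3

    def __post_init__(self) -> None:
        if self.name not in ENCODER_REGISTRY:
            raise ConfigurationError(
                f"unknown encoder {self.name!r}; registered: "
                f"{sorted(ENCODER_REGISTRY)}"
            )

    @property
    def prefix(self) -> str:
        return ENCODER_REGISTRY[self.name].prefix

    def n_features(self, length: int) -> int:
        return ENCODER_REGISTRY[self.name].n_features(length, self)

    def encode(self, seq: "DnaSequence | str") -> np.ndarray:
        return ENCODER_REGISTRY[self.name].encode(seq, self)


@dataclass(frozen=True)
class _EncoderEntry:
    prefix: str
    encode: Callable[["DnaSequence | str", EncoderSpec], np.ndarray]
    n_features: Callable[[int, EncoderSpec], int]


ENCODER_REGISTRY: dict[str, _EncoderEntry] = {}


def register_encoder(
    name: str,
    prefix: str,
    encode: Callable[["DnaSequence | str", EncoderSpec], np.ndarray],
    n_features: Callable[[int, EncoderSpec], int],
) -> None:
    """Register an encoder under ``name`` (used for tests and extensions)."""
    ENCODER_REGISTRY[name] = _EncoderEntry(prefix, encode, n_features)


register_encoder("onehot", "one-hot", lambda s, _: encode_onehot(s), lambda L, _: 4 * L)
register_encoder("eiip", "EIIP", lambda s, _: encode_eiip(s), lambda L, _: L)
register_encoder("ncp", "NCP", lambda s, _: encode_ncp(s), lambda L, _: 3 * L)
register_encoder(
    "enac",
    "ENAC",
    lambda s, spec: encode_enac(s, spec.window_size),
    lambda L, spec: 4 * (L - spec.window_size + 1),
)
register_encoder("anf", "ANF", lambda s, _: encode_anf(s), lambda L, _: L)
register_encoder("nac", "NAC", lambda s, _: encode_nac(s), lambda L, _: 4)
register_encoder(
    "kmer",
    "Kmer",
    lambda s, spec: encode_kmer(s, spec.k),
    lambda L, spec: 4**spec.k,
)


@dataclass
class FeatureMatrix:
    """Samples × named features, the learners' input."""

    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("feature matrix must be 2-dimensional")
        if self.values.shape[1] != len(self.feature_names):
            raise ConfigurationError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=self.feature_names).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        return cls(df.to_numpy(dtype=float), list(df.columns))


def feature_names(specs: Sequence[EncoderSpec], length: int) -> list[str]:
    """Column names for the concatenation of ``specs`` at a given length."""
    names: list[str] = []
    for spec in specs:
        names.extend(
            f"{spec.prefix}_{i}" for i in range(1, spec.n_features(length) + 1)
        )
    return names


def encode_sequences(
    sequences: Sequence["DnaSequence | str"],
    specs: Sequence[EncoderSpec],
) -> FeatureMatrix:
    """Encode a batch of equal-length sequences with the given encoders."""
    if not specs:
        raise ConfigurationError("at least one encoder spec is required")
    if not sequences:
        raise ConfigurationError("no sequences to encode")
    length = len(sequences[0].residues if isinstance(sequences[0], DnaSequence) else sequences[0])
    rows = [
        np.concatenate([spec.encode(seq) for spec in specs]) for seq in sequences
    ]
    return FeatureMatrix(np.vstack(rows), feature_names(specs, length))


def encode_dataset(dataset: LabeledDataset, specs: Sequence[EncoderSpec]) -> FeatureMatrix:
    """Encode every sequence of a labeled dataset, preserving row order."""
    return encode_sequences(dataset.sequences, specs)


def specs_from_names(names: Iterable[str]) -> list[EncoderSpec]:
    """Build default-parameter specs from encoder names (CLI convenience)."""
    return [EncoderSpec(name.strip().lower()) for name in names]
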
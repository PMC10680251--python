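"""Reading, validating and writing fixed-length DNA sequence datasets.

6mA benchmark datasets follow a two-file convention: one FASTA of positive
windows (each centred on a methylated adenine) and one FASTA of negative
windows, all of a common length (41 nt in the standard benchmarks).
:func:`load_labeled` reads such a pair into a :class:`LabeledDataset`
(positives first, label 1).  A single-file dialect with ``|1`` / ``|0``
label suffixes on the headers is also accepted via
:func:`load_labeled_single`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    AlphabetError,
    DatasetConsistencyError,
    EmptyInputError,
    FastaParseError,
)

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
_DNA_SET = frozenset(DNA_ALPHABET)

#: Window length of the standard 6mA benchmark datasets.
DEFAULT_LENGTH = 41


@dataclass(frozen=True)
class DnaSequence:
    """A DNA sequence record: an identifier plus its residues.

    Residues are uppercased on construction.  Alphabet validation is the
    reader's job (see ``alphabet_policy`` in :func:`read_fasta`) so that the
    opt-in ambiguity policy can still build instances containing masked
    characters; sequences produced by the default readers contain only
    A/C/G/T.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """An ordered set of equal-length sequences with binary 6mA labels.

    ``labels[i] == 1`` means sequence *i* contains a 6mA site.
    """

    sequences: list[DnaSequence]
    labels: np.ndarray
    uniform_length: int = field(default=0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.sequences) != self.labels.shape[0]:
            raise DatasetConsistencyError(
                f"{len(self.sequences)} sequences but {self.labels.shape[0]} labels"
            )
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise DatasetConsistencyError(
                f"sequences have mixed lengths {sorted(lengths)}"
            )
        if self.uniform_length == 0 and lengths:
            self.uniform_length = lengths.pop()
        elif lengths and lengths != {self.uniform_length}:
            raise DatasetConsistencyError(
                f"sequences have length {lengths.pop()}, expected {self.uniform_length}"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        """Row-select a new dataset (order follows ``indices``)."""
        idx = np.asarray(indices, dtype=np.intp)
        return LabeledDataset(
            [self.sequences[i] for i in idx],
            self.labels[idx],
            self.uniform_length,
        )


def _validate_alphabet(rec_id: str, residues: str, policy: str) -> None:
    if policy == "mask":
        return
    for ch in residues:
        if ch not in _DNA_SET:
            raise AlphabetError(
                f"record {rec_id!r}: character {ch!r} is not in the DNA "
                f"alphabet {{A,C,G,T}} (use alphabet_policy='mask' to keep "
                f"ambiguity codes as zero-feature positions)"
            )


def _prescan_fasta(path: Path) -> None:
    """Reject files Biopython would silently mis-parse, naming the line."""
    saw_header = False
    saw_any = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            saw_any = True
            if stripped.startswith(">"):
                saw_header = True
            elif not saw_header:
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before the first "
                    f"'>' header"
                )
    if not saw_any:
        raise EmptyInputError(f"{path}: file is empty")


def read_fasta(
    path: str | Path,
    length_policy: str = "require_uniform",
    alphabet_policy: str = "reject",
) -> list[DnaSequence]:
    """Read a FASTA file into validated :class:`DnaSequence` records.

    Parameters
    ----------
    path
        FASTA file ('>' headers, sequence lines; multi-line records allowed).
    length_policy
        ``"require_uniform"`` raises if records have unequal lengths;
        ``"any"`` accepts mixed lengths.
    alphabet_policy
        ``"reject"`` (default) raises :class:`~sixmastack.errors.AlphabetError`
        on any residue outside A/C/G/T (after uppercasing); ``"mask"`` keeps
        such residues, which downstream encoders treat as zero contributions.
        U is always rejected under the default policy: these are DNA data.
    """
    if length_policy not in ("require_uniform", "any"):
        raise ValueError(f"unknown length_policy {length_policy!r}")
    if alphabet_policy not in ("reject", "mask"):
        raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")
    path = Path(path)
    _prescan_fasta(path)
    records: list[DnaSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        _validate_alphabet(rec.id, residues, alphabet_policy)
        records.append(DnaSequence(rec.id, residues))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records found")
    if length_policy == "require_uniform":
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise DatasetConsistencyError(
                f"{path}: records have mixed lengths {sorted(lengths)} but "
                f"uniform length is required"
            )
    return records


def load_labeled(
    pos_path: str | Path,
    neg_path: str | Path,
    expected_length: int | None = None,
    require_central_adenine: bool = False,
) -> LabeledDataset:
    """Load the positive/negative two-file convention into one dataset.

    Positives come first with label 1, then negatives with label 0; record
    order within each file is preserved.  Both files must share one sequence
    length (optionally checked against ``expected_length``, e.g. 41).

    ``require_central_adenine=True`` additionally asserts that the central
    residue of every window is A — the benchmark datasets centre windows on
    the candidate methylation site, but this is not enforced by default.
    """
    positives = read_fasta(pos_path, length_policy="require_uniform")
    negatives = read_fasta(neg_path, length_policy="require_uniform")
    lp, ln = len(positives[0]), len(negatives[0])
    if lp != ln:
        raise DatasetConsistencyError(
            f"positive records are {lp} nt but negative records are {ln} nt"
        )
    if expected_length is not None and lp != expected_length:
        raise DatasetConsistencyError(
            f"records are {lp} nt, expected {expected_length} nt"
        )
    sequences = positives + negatives
    if require_central_adenine:
        center = lp // 2  # 0-based index of position (L+1)/2 for odd L
        for seq in sequences:
            if seq.residues[center] != "A":
                raise DatasetConsistencyError(
                    f"record {seq.id!r}: central residue "
                    f"{seq.residues[center]!r} is not adenine"
                )
    labels = np.concatenate(
        [np.ones(len(positives), dtype=np.int64), np.zeros(len(negatives), dtype=np.int64)]
    )
    logger.info(
        "loaded %d positive and %d negative sequences of length %d nt",
        len(positives), len(negatives), lp,
    )
    return LabeledDataset(sequences, labels, lp)


def load_labeled_single(path: str | Path) -> LabeledDataset:
    """Load a single FASTA whose headers end in ``|1`` (6mA) or ``|0``.

    A convenience dialect for single-upload workflows; records keep their
    file order (no positives-first reordering).
    """
    records = read_fasta(path, length_policy="require_uniform")
    labels = []
    for rec in records:
        tag = rec.id.rsplit("|", 1)
        if len(tag) != 2 or tag[1] not in ("0", "1"):
            raise DatasetConsistencyError(
                f"record {rec.id!r}: header does not end in '|0' or '|1'"
            )
        labels.append(int(tag[1]))
    return LabeledDataset(records, np.asarray(labels), len(records[0]))


def write_fasta(sequences: Iterable[DnaSequence], path: str | Path) -> None:
    """Write records as plain FASTA (one sequence line per record)."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")


def write_predictions(
    records: Iterable[tuple[str, float, int]],
    path: str | Path,
) -> None:
    """Write (id, probability, predicted_label) rows as a TSV file.

    Probabilities are rendered with 4 decimal places; order is preserved.
    """
    with open(path, "w") as fh:
        fh.write("id\tprobability\tpredicted_label\n")
        for rec_id, prob, label in records:
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"probability {prob} outside [0, 1] for {rec_id!r}")
            if label not in (0, 1):
                raise ValueError(f"label {label} not binary for {rec_id!r}")
            fh.write(f"{rec_id}\t{prob:.4f}\t{label}\n")
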
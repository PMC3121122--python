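"""Conjoint-triad and amino-acid-composition encodings of protein sequences.

The conjoint triad feature (CTF) groups the 20 standard amino acids into seven
classes by side-chain dipole and volume, slides a width-3 window over the
sequence, and records the frequency of each ordered class triple.  The result
is a 343-dimensional (7x7x7) frequency vector that captures both composition
and local sequence order — the signal carried by adjacent catalytic residues.

The amino-acid composition (AAC) is the classical 20-dimensional single-residue
frequency vector, kept as a baseline encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_CLASSES",
    "STANDARD_RESIDUES",
    "AMBIGUITY_RESIDUES",
    "ProteinRecord",
    "CTFVector",
    "AACVector",
    "classify_residue",
    "triad_index",
    "encode_ctf",
    "encode_aac",
    "ctf_feature_names",
    "encode_records",
]

#: The seven conjoint-triad classes, by side-chain dipole and volume.
AMINO_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard one-letter codes accepted in input sequences.
AMBIGUITY_RESIDUES: str = "BJOUXZ"

_CLASS_OF: dict[str, int] = {
    res: idx + 1 for idx, group in enumerate(AMINO_CLASSES) for res in group
}

N_TRIADS = 7 * 7 * 7


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier.

    Lower-case residues are upper-cased on construction; any character outside
    the 20 standard codes plus the declared ambiguity set is rejected.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = set(STANDARD_RESIDUES) | set(AMBIGUITY_RESIDUES)
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue code(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class CTFVector:
    """343-element conjoint-triad frequency vector for one sequence."""

    values: np.ndarray
    n_triads: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (N_TRIADS,):
            raise ValueError(f"CTF vector must have length {N_TRIADS}")


@dataclass(frozen=True)
class AACVector:
    """20-element amino-acid composition vector."""

    values: np.ndarray = field()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (20,):
            raise ValueError("AAC vector must have length 20")


def classify_residue(residue: str) -> int | None:
    """Map a one-letter residue code to its conjoint-triad class (1..7).

    Returns ``None`` for ambiguity codes and anything else outside the fixed
    partition, so callers can skip windows rather than fail.
    """
    return _CLASS_OF.get(residue.upper())


def triad_index(c1: int, c2: int, c3: int) -> int:
    """Row-major cell index (0..342) of the ordered class triple (c1, c2, c3)."""
    for c in (c1, c2, c3):
        if not 1 <= c <= 7:
            raise ValueError(f"class index {c} outside 1..7")
    return (c1 - 1) * 49 + (c2 - 1) * 7 + (c3 - 1)


def ctf_feature_names() -> list[str]:
    """Column names 111..777 in the fixed row-major triad order."""
    return [
        f"{c1}{c2}{c3}"
        for c1 in range(1, 8)
        for c2 in range(1, 8)
        for c3 in range(1, 8)
    ]


def encode_ctf(record: ProteinRecord, minmax: bool = False) -> CTFVector:
    """Encode one sequence as a conjoint-triad frequency vector.

    Every window of three consecutive classifiable residues increments its
    triad cell; counts are divided by the number of counted windows.  Windows
    containing an ambiguity code are skipped and excluded from the denominator.

    With ``minmax=True`` the frequencies are additionally rescaled as
    (f - min) / max, the normalization of the original triad descriptor.
    """
    classes = [classify_residue(r) for r in record.sequence]
    counts = np.zeros(N_TRIADS, dtype=float)
    n = 0
    for i in range(len(classes) - 2):
        c1, c2, c3 = classes[i], classes[i + 1], classes[i + 2]
        if c1 is None or c2 is None or c3 is None:
            continue
        counts[triad_index(c1, c2, c3)] += 1
        n += 1
    if n == 0:
        raise ValueError(
            f"record {record.id!r}: no window of three classifiable residues"
        )
    values = counts / n
    if minmax:
        values = (values - values.min()) / values.max()
    return CTFVector(values=values, n_triads=n)


def encode_aac(record: ProteinRecord) -> AACVector:
    """Encode one sequence as single-residue frequencies over the 20 standard
    codes; ambiguity codes are excluded from numerator and denominator."""
    counts = np.zeros(20, dtype=float)
    pos = {res: i for i, res in enumerate(STANDARD_RESIDUES)}
    n = 0
    for r in record.sequence:
        i = pos.get(r)
        if i is not None:
            counts[i] += 1
            n += 1
    if n == 0:
        raise ValueError(f"record {record.id!r}: no standard residue")
    return AACVector(values=counts / n)


def encode_records(
    records: list[ProteinRecord], encoder: str = "ctf", minmax: bool = False
) -> pd.DataFrame:
    """Encode many records into a feature table (rows = record ids).

    ``encoder`` is ``"ctf"`` (343 columns named 111..777) or ``"aac"``
    (20 columns named by residue letter).
    """
    if encoder == "ctf":
        columns = ctf_feature_names()
        rows = [encode_ctf(r, minmax=minmax).values for r in records]
    elif encoder == "aac":
        columns = list(STANDARD_RESIDUES)
        rows = [encode_aac(r).values for r in records]
    else:
        raise ValueError(f"unknown encoder {encoder!r}")
    ids = [r.id for r in records]
    return pd.DataFrame(np.asarray(rows), index=pd.Index(ids, name="id"), columns=columns)
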
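"""File formats: FASTA in, TSV feature/label/prediction tables, JSON trees.

Feature tables are plain tab-separated text with a mandatory header (first
column ``id``, then one column per feature) so they stay diffable; label
files are two-column TSV (id, dotted label).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .ctf import ProteinRecord
from .hierarchy import _LABEL_RE

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "read_feature_table",
    "write_feature_table",
]


def _validate_fasta_structure(path: Path) -> None:
    """Structural pre-scan with line numbers: non-empty, header before any
    sequence, no duplicate ids."""
    seen: set[str] = set()
    saw_header = False
    any_content = False
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            any_content = True
            if stripped.startswith(">"):
                saw_header = True
                rec_id = stripped[1:].split()[0] if stripped[1:].split() else ""
                if not rec_id:
                    raise ValueError(f"{path}:{lineno}: header without an id")
                if rec_id in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate id {rec_id!r}")
                seen.add(rec_id)
            elif not saw_header:
                raise ValueError(f"{path}:{lineno}: sequence data before any header")
    if not any_content:
        raise ValueError(f"{path}: empty FASTA file")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a (possibly line-wrapped) multi-record FASTA file.

    Record order is preserved; the id is the first whitespace-delimited token
    after ``>``.  Structural problems are reported with line numbers.
    """
    path = Path(path)
    _validate_fasta_structure(path)
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (id, dotted label); optional ``id<TAB>label`` header.

    Malformed rows are reported with their line number.
    """
    path = Path(path)
    out: dict[str, str] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and [p.lower() for p in parts[:2]] == ["id", "label"]:
                continue
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            rec_id, label = parts
            if not rec_id:
                raise ValueError(f"{path}:{lineno}: empty id")
            if not _LABEL_RE.match(label):
                raise ValueError(f"{path}:{lineno}: malformed label {label!r}")
            if rec_id in out:
                raise ValueError(f"{path}:{lineno}: duplicate id {rec_id!r}")
            out[rec_id] = label
    if not out:
        raise ValueError(f"{path}: no labels found")
    return out


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as out:
        out.write("id\tlabel\n")
        for rec_id, label in labels.items():
            out.write(f"{rec_id}\t{label}\n")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Feature table as TSV: header row, first column ``id``."""
    table.to_csv(path, sep="\t", index=True, index_label="id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="id")
    if table.empty:
        raise ValueError(f"{path}: empty feature table")
    return table
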
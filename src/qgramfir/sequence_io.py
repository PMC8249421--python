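"""FASTA input, sequence normalization and validation, tabular output helpers.

Sequences are used exactly as given (sense strand); no reverse-complement
canonicalization is applied.  Uppercase normalization maps RNA 'U' to 'T';
the ambiguity code 'N' is retained and handled downstream (a q-gram window
touching an 'N' matches no bin).  All other IUPAC codes are rejected loudly.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

VALID_CHARS = frozenset("ACGTN")


class SequenceIOError(ValueError):
    """Raised for malformed FASTA input or inconsistent sequence sets."""


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase a raw sequence, map U->T, and reject illegal characters.

    Idempotent: normalizing an already-normalized sequence is a no-op.
    """
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_CHARS
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise SequenceIOError(
            f"record {record_id!r}: illegal character {seq[pos]!r} at position {pos + 1} "
            f"(allowed: A, C, G, T, N, U)"
        )
    if not seq:
        raise SequenceIOError(f"record {record_id!r}: empty sequence")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_sequence(self.seq, self.id))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SequenceSet:
    """An ordered collection of equal-length sequences (m >= 1 records)."""

    records: list[SequenceRecord]
    n: int = field(init=False)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SequenceIOError(f"duplicate sequence ids: {sorted(dupes)}")
        self.n = validate_equal_length(self.records)

    @property
    def m(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def validate_equal_length(records: Sequence[SequenceRecord]) -> int:
    """Return the shared length n of all records, or raise listing the lengths seen."""
    if not records:
        raise SequenceIOError("no sequences")
    lengths = sorted({len(r) for r in records})
    if len(lengths) > 1:
        raise SequenceIOError(
            f"sequences have unequal lengths {lengths}; equal-length input is required"
        )
    return lengths[0]


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a (possibly gzipped) multi-FASTA file into a validated SequenceSet.

    Headers are split at the first whitespace; the first token is the id.
    """
    path = Path(path)
    if not path.exists():
        raise SequenceIOError(f"no such file: {path}")
    with _open_maybe_gzip(path) as handle:
        records = [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise SequenceIOError(f"no sequences in {path}")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet | Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records to a plain-text FASTA file, wrapping lines at ``width``."""
    records = list(seqs)
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for start in range(0, len(rec.seq), width):
                out.write(rec.seq[start : start + width] + "\n")


def write_matrix_tsv(values: np.ndarray, ids: Sequence[str], path: str | Path) -> None:
    """Write a square matrix with row/column id headers as TSV (12 sig. digits)."""
    values = np.asarray(values)
    with open(path, "w") as out:
        out.write("id\t" + "\t".join(ids) + "\n")
        for rid, row in zip(ids, values):
            out.write(rid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square id-labelled TSV matrix written by :func:`write_matrix_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    return np.asarray(rows, dtype=float), header


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as out:
        json.dump(obj, out, indent=2, sort_keys=True)
        out.write("\n")
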
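"""Standard-format I/O for assembled transcripts and count tables.

Assemblies arrive as plain FASTA with Trinity-style identifiers
(``compX_cY_seqZ``); fragment counts arrive as a four-column TSV.  The FASTA
reader is deliberately strict — duplicate identifiers and malformed records
are rejected with the offending line number — because downstream truth
bookkeeping keys on unique ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

COUNTS_COLUMNS = ["transcript_id", "length", "count_control", "count_treated"]


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript: identifier plus uppercase DNA sequence."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case-insensitive)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a FASTA file into TranscriptRecords, preserving input order.

    Sequences are uppercased and multi-line records are concatenated.
    Raises ``ValueError`` with the line number for sequence data before the
    first header or for a record with an empty sequence, and names the
    identifier for duplicates.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    current_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(
                f"record '{current_id}' (line {current_line}) has an empty sequence"
            )
        if current_id in seen:
            raise ValueError(f"duplicate transcript id '{current_id}'")
        seen.add(current_id)
        records.append(TranscriptRecord(current_id, seq))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise ValueError(f"empty FASTA header at line {lineno}")
                current_line = lineno
                chunks = []
            else:
                if current_id is None:
                    raise ValueError(
                        f"sequence data before first FASTA header at line {lineno}"
                    )
                chunks.append(line.upper())
        _flush()
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped to ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV (transcript_id, length, count_control, count_treated)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"counts table is missing columns: {missing}")
    return table[COUNTS_COLUMNS].copy()


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    table[COUNTS_COLUMNS].to_csv(path, sep="\t", index=False)


def records_to_dict(records: Sequence[TranscriptRecord]) -> dict[str, str]:
    return {rec.id: rec.seq for rec in records}
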
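"""Synthetic transcriptome data with planted ground truth.

The raw sequencing data behind a de novo assembly study is rarely needed
to test its post-processing stages; what matters is data with the same
structure and a known answer.  This module generates:

* host ("coding") transcripts — 5'UTR + ORF + 3'UTR, where the ORF is
  ``ATG`` + codons drawn i.i.d. from a known, skewed codon-usage table + a
  stop codon, and UTRs are i.i.d. from a mononucleotide model.  A fraction
  of transcripts is reverse-complemented so the ORF sits on the minus
  strand, exercising six-frame search.
* contaminant transcripts — drawn from a compositionally divergent order-0
  or order-1 nucleotide chain, emulating sequences from another organism.
* two-condition fragment-count tables — negative-binomial counts (mean m,
  variance m + dispersion * m^2) with planted log2 fold changes.

Everything is reproducible from a single integer seed, and every generated
transcript is covered by a truth table recording contaminant status,
planted ORF coordinates and strand, and the true fold change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import TranscriptRecord, revcomp
from .orf import STOP_CODONS, SENSE_CODONS, CodonUsageTable

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Presets: the default study conditions for tests and the acceptance run.
# ---------------------------------------------------------------------------

def skewed_codon_table() -> CodonUsageTable:
    """A strongly GC3-biased codon-usage table used as the generation truth.

    Codon weight depends on the third base (C:6, G:3, A:1, T:1), a caricature
    of the GC3 skew real fungal transcriptomes show.  Total-variation
    distance to the uniform table is about 0.32, far enough for
    codon-preference training to be identifiable.
    """
    third_weight = {"C": 6.0, "G": 3.0, "A": 1.0, "T": 1.0}
    raw = {c: third_weight[c[2]] for c in SENSE_CODONS}
    total = sum(raw.values())
    return CodonUsageTable(freq={c: w / total for c, w in raw.items()})


#: mononucleotide model for UTRs: slightly AT-rich, as fungal UTRs are
UTR_MONO = {"A": 0.30, "C": 0.20, "G": 0.20, "T": 0.30}

#: order-1 chain for host-like (non-coding decoy) sequence: mild CpG
#: depletion around a balanced composition
HOST_CHAIN = {
    "initial": {"A": 0.28, "C": 0.22, "G": 0.22, "T": 0.28},
    "transition": {
        "A": {"A": 0.30, "C": 0.22, "G": 0.24, "T": 0.24},
        "C": {"A": 0.30, "C": 0.24, "G": 0.12, "T": 0.34},
        "G": {"A": 0.26, "C": 0.24, "G": 0.24, "T": 0.26},
        "T": {"A": 0.22, "C": 0.24, "G": 0.26, "T": 0.28},
    },
}

#: order-1 chain for contaminants: GC-rich with strong CpG and TpA
#: avoidance — a compositional signature far from HOST_CHAIN
CONTAMINANT_CHAIN = {
    "initial": {"A": 0.18, "C": 0.32, "G": 0.32, "T": 0.18},
    "transition": {
        "A": {"A": 0.10, "C": 0.45, "G": 0.40, "T": 0.05},
        "C": {"A": 0.25, "C": 0.40, "G": 0.05, "T": 0.30},
        "G": {"A": 0.10, "C": 0.40, "G": 0.40, "T": 0.10},
        "T": {"A": 0.03, "C": 0.40, "G": 0.47, "T": 0.10},
    },
}


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated transcript."""

    transcript_id: str
    is_contaminant: bool
    orf_start: int | None = None  # 0-based, forward strand
    orf_end: int | None = None  # half-open; includes the stop codon
    orf_strand: str | None = None
    true_log2fc: float = 0.0


@dataclass
class SyntheticTruth:
    """Truth table covering every generated transcript exactly once."""

    records: dict[str, TruthRecord] = field(default_factory=dict)
    seed: int | None = None
    params: dict = field(default_factory=dict)
    true_table: CodonUsageTable | None = None

    def add(self, rec: TruthRecord) -> None:
        if rec.transcript_id in self.records:
            raise ValueError(f"duplicate truth record '{rec.transcript_id}'")
        self.records[rec.transcript_id] = rec

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        merged = SyntheticTruth(seed=self.seed, params={**self.params, **other.params},
                                true_table=self.true_table or other.true_table)
        for rec in list(self.records.values()) + list(other.records.values()):
            merged.add(rec)
        return merged

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id,
                    "is_contaminant": r.is_contaminant,
                    "orf_start": r.orf_start,
                    "orf_end": r.orf_end,
                    "orf_strand": r.orf_strand,
                    "true_log2fc": r.true_log2fc,
                }
                for r in self.records.values()
            ]
        )

    def write(self, tsv_path: str | Path, json_path: str | Path) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        sidecar = {
            "seed": self.seed,
            "params": self.params,
            "true_codon_table": self.true_table.freq if self.true_table else None,
        }
        with open(json_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)


def _validate_freqs(model: Mapping[str, float], name: str) -> np.ndarray:
    vec = np.array([model.get(b, 0.0) for b in _BASES], dtype=float)
    if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} frequencies must be non-negative and sum to 1 (within 1e-9)")
    return vec


def _sample_iid(rng: np.random.Generator, mono: np.ndarray, n: int) -> str:
    idx = rng.choice(4, size=n, p=mono)
    return "".join(_BASES[i] for i in idx)


def generate_host_transcripts(
    n: int,
    true_table: CodonUsageTable | None = None,
    orf_len_range: tuple[int, int] = (300, 900),
    utr_len_range: tuple[int, int] = (20, 200),
    utr_model: Mapping[str, float] = UTR_MONO,
    seed: int = 0,
    antisense_frac: float = 0.2,
    id_offset: int = 0,
) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Generate coding transcripts (UTR + planted ORF + UTR).

    ``orf_len_range`` bounds the total ORF length in nt, start and stop
    codons included; the realized length is a multiple of 3.  Truth
    coordinates are forward-strand, 0-based half-open, and include the stop
    codon.  ``antisense_frac`` of transcripts carry the ORF on the minus
    strand.
    """
    if true_table is None:
        true_table = skewed_codon_table()
    utr_vec = _validate_freqs(utr_model, "utr_model")
    lo, hi = orf_len_range
    if lo < 9:
        raise ValueError("orf_len_range must allow at least ATG + 1 codon + stop (9 nt)")
    rng = np.random.default_rng(seed)
    codon_list = list(SENSE_CODONS)
    codon_p = np.array([true_table.freq.get(c, 0.0) for c in codon_list])
    if abs(codon_p.sum() - 1.0) > 1e-9:
        raise ValueError("true_table frequencies must sum to 1 (within 1e-9)")
    stops = list(STOP_CODONS)

    records: list[TranscriptRecord] = []
    truth = SyntheticTruth(seed=seed, true_table=true_table,
                           params={"n_host": n, "orf_len_range": list(orf_len_range),
                                   "utr_len_range": list(utr_len_range),
                                   "antisense_frac": antisense_frac})
    for i in range(n):
        total_orf = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        n_body = total_orf // 3 - 2  # codons between ATG and stop
        utr5 = int(rng.integers(utr_len_range[0], utr_len_range[1] + 1))
        utr3 = int(rng.integers(utr_len_range[0], utr_len_range[1] + 1))
        body_idx = rng.choice(len(codon_list), size=n_body, p=codon_p)
        body = "".join(codon_list[j] for j in body_idx)
        stop = stops[int(rng.integers(0, 3))]
        seq = _sample_iid(rng, utr_vec, utr5) + "ATG" + body + stop + _sample_iid(rng, utr_vec, utr3)
        start, end = utr5, utr5 + total_orf
        strand = "+"
        if rng.random() < antisense_frac:
            L = len(seq)
            seq = revcomp(seq)
            start, end = L - end, L - start
            strand = "-"
        tid = f"comp{id_offset + i}_c0_seq1"
        records.append(TranscriptRecord(tid, seq))
        truth.add(TruthRecord(tid, is_contaminant=False, orf_start=start,
                              orf_end=end, orf_strand=strand))
    return records, truth


def _chain_params(model: Mapping) -> tuple[np.ndarray, np.ndarray | None]:
    """Normalize an order-0 or order-1 model spec to numpy parameters."""
    if "transition" in model:
        init = _validate_freqs(model.get("initial", {b: 0.25 for b in _BASES}), "initial")
        trans = np.zeros((4, 4))
        for i, b in enumerate(_BASES):
            trans[i] = _validate_freqs(model["transition"][b], f"transition[{b}]")
        return init, trans
    return _validate_freqs(model, "order-0 model"), None


def sample_chain_sequence(rng: np.random.Generator, model: Mapping, length: int) -> str:
    """One sequence from an order-0 or order-1 nucleotide chain."""
    init, trans = _chain_params(model)
    if trans is None:
        return _sample_iid(rng, init, length)
    out = np.empty(length, dtype=np.int64)
    if length == 0:
        return ""
    out[0] = rng.choice(4, p=init)
    # inverse-CDF stepping keeps the per-base work trivial
    cdf = np.cumsum(trans, axis=1)
    u = rng.random(length)
    for i in range(1, length):
        out[i] = np.searchsorted(cdf[out[i - 1]], u[i])
    return "".join(_BASES[i] for i in out)


def generate_contaminants(
    n: int,
    model: Mapping = CONTAMINANT_CHAIN,
    len_range: tuple[int, int] = (600, 2000),
    seed: int = 0,
    id_prefix: str = "contam",
) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Generate contaminant transcripts from a divergent nucleotide chain."""
    _chain_params(model)  # validate up front
    rng = np.random.default_rng(seed)
    records = []
    truth = SyntheticTruth(seed=seed, params={"n_contaminant": n, "len_range": list(len_range)})
    for i in range(n):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        seq = sample_chain_sequence(rng, model, length)
        tid = f"{id_prefix}{i}_c0_seq1"
        records.append(TranscriptRecord(tid, seq))
        truth.add(TruthRecord(tid, is_contaminant=True))
    return records, truth


def generate_counts(
    records: list[TranscriptRecord],
    truth: SyntheticTruth,
    base_mean: float = 50.0,
    dispersion: float = 0.05,
    lib_size_control: float = 1e6,
    lib_size_treated: float = 1e6,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-condition negative-binomial fragment counts with planted fold changes.

    Control mean is ``base_mean * (length / 1000) * (lib_size_control / 1e6)``;
    the treated mean is additionally multiplied by ``2 ** true_log2fc``.
    Variance follows m + dispersion * m^2.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        if rec.id not in truth.records:
            raise ValueError(f"no truth record for '{rec.id}'")
        lfc = truth.records[rec.id].true_log2fc
        m_control = base_mean * (len(rec.seq) / 1000.0) * (lib_size_control / 1e6)
        m_treated = base_mean * (len(rec.seq) / 1000.0) * (lib_size_treated / 1e6) * 2.0**lfc
        counts = []
        for m in (m_control, m_treated):
            if m <= 0:
                counts.append(0)
                continue
            size = 1.0 / dispersion  # NB shape; var = m + m^2/size
            p = size / (size + m)
            counts.append(int(rng.negative_binomial(size, p)))
        rows.append(
            {
                "transcript_id": rec.id,
                "length": len(rec.seq),
                "count_control": counts[0],
                "count_treated": counts[1],
            }
        )
    return pd.DataFrame(rows, columns=["transcript_id", "length", "count_control", "count_treated"])


def plant_fold_changes(
    truth: SyntheticTruth,
    de_fraction: float = 0.1,
    magnitudes: tuple[float, ...] = (2.0, 3.0),
    seed: int = 0,
) -> SyntheticTruth:
    """Assign true log2 fold changes: a fraction of non-contaminant
    transcripts get +/- one of ``magnitudes``, the rest stay at 0."""
    rng = np.random.default_rng(seed)
    new = SyntheticTruth(seed=truth.seed, params=dict(truth.params), true_table=truth.true_table)
    new.params["de_fraction"] = de_fraction
    for tid, rec in truth.records.items():
        lfc = 0.0
        if not rec.is_contaminant and rng.random() < de_fraction:
            mag = magnitudes[int(rng.integers(0, len(magnitudes)))]
            lfc = mag if rng.random() < 0.5 else -mag
        new.add(TruthRecord(tid, rec.is_contaminant, rec.orf_start, rec.orf_end,
                            rec.orf_strand, true_log2fc=lfc))
    return new
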
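"""Coding-sequence prediction by codon preference with iterative self-training.

Coding regions use synonymous codons unevenly, and the skew is consistent
within a transcriptome.  A reading frame scored against a trained
codon-usage table therefore separates genuine CDS from spurious open
reading frames without homology evidence.  The score of a candidate is a
log-likelihood ratio in bits,

    score = sum_c log2( q_c / b_c )

over its sense codons, where q_c is the trained frequency of codon c and
b_c a background (uniform over the 61 sense codons, or derived from the
transcript's own mononucleotide composition).

The codon table is not known up front, so it is learned by self-training:
bootstrap a table from the single longest open reading frame of every
transcript, then alternate scoring all candidates, keeping the best-scoring
CDS per transcript, and retraining on the kept set.  A handful of
iterations (four by default) suffices; training stops early once the table
stops moving in L1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log2

import numpy as np

from .io import TranscriptRecord, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
_ALL_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
SENSE_CODONS = tuple(c for c in _ALL_CODONS if c not in STOP_CODONS)

# standard genetic code, indexed by codon
_CODON_AA = dict(
    zip(
        _ALL_CODONS,
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    )
)


def translate(codons: list[str]) -> str:
    """Amino-acid string for a codon list; ambiguous codons become X."""
    return "".join(_CODON_AA.get(c, "X") for c in codons)


@dataclass(frozen=True)
class CodonUsageTable:
    """Frequencies over the 61 sense codons, with training provenance.

    ``freq`` maps each sense codon to a frequency (sums to 1); with a
    positive pseudocount every frequency is strictly positive, which keeps
    log-likelihood scores finite.
    """

    freq: dict[str, float]
    pseudocount: float = 0.0
    iteration: int = 0
    n_training_codons: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.freq) - set(SENSE_CODONS)
        if unknown:
            raise ValueError(f"non-sense codons in table: {sorted(unknown)}")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"codon frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("negative codon frequency")

    def get(self, codon: str) -> float:
        return self.freq.get(codon, 0.0)

    def as_vector(self) -> np.ndarray:
        return np.array([self.freq.get(c, 0.0) for c in SENSE_CODONS])

    def l1_distance(self, other: "CodonUsageTable") -> float:
        return float(np.abs(self.as_vector() - other.as_vector()).sum())

    def tv_distance(self, other: "CodonUsageTable") -> float:
        """Total-variation distance (half the L1 distance)."""
        return 0.5 * self.l1_distance(other)


def uniform_table() -> CodonUsageTable:
    return CodonUsageTable(freq={c: 1.0 / 61.0 for c in SENSE_CODONS})


@dataclass(frozen=True)
class OrfCall:
    """A candidate or final coding region on a transcript.

    ``start``/``end`` are 0-based half-open forward-strand nucleotide
    coordinates regardless of ``strand``; ``frame`` is the reading frame on
    the strand the ORF is read from.  ``end - start`` is divisible by 3 and
    the run contains no internal stop codon.
    """

    transcript_id: str
    start: int
    end: int
    strand: str
    frame: int
    has_start: bool
    has_stop: bool
    peptide: str
    score: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def nt_seq(self, transcript_seq: str) -> str:
        """Coding-strand nucleotide sequence of the call."""
        sub = transcript_seq[self.start : self.end]
        return sub if self.strand == "+" else revcomp(sub)

    def codons(self, transcript_seq: str) -> list[str]:
        nt = self.nt_seq(transcript_seq)
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]


def find_candidate_orfs(
    record: TranscriptRecord,
    min_len: int = 300,
    require_start: bool = True,
    both_strands: bool = True,
) -> list[OrfCall]:
    """Enumerate maximal open reading frames in up to six frames.

    In each frame, a run extends from the first ATG after the previous stop
    (or from the frame start when ``require_start`` is false) to the next
    in-frame stop codon, inclusive; a trailing run without a stop is
    reported with ``has_stop=False``.  Runs shorter than ``min_len``
    nucleotides (stop included when present) are dropped.  Minus-strand
    runs are reported in forward-strand coordinates.
    """
    if min_len % 3 != 0:
        raise ValueError("min_len must be divisible by 3")
    calls: list[OrfCall] = []
    L = len(record.seq)
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        seq = record.seq if strand == "+" else revcomp(record.seq)
        for frame in range(3):
            n_codons = (L - frame) // 3
            if n_codons == 0:
                continue
            codons = [seq[frame + 3 * i : frame + 3 * i + 3] for i in range(n_codons)]
            run_start: int | None = None  # codon index where the current run begins
            i = 0
            seg_begin = 0  # first codon index of the current inter-stop segment
            while i <= n_codons:
                at_end = i == n_codons
                codon = None if at_end else codons[i]
                if not at_end and codon in STOP_CODONS:
                    if run_start is None and not require_start:
                        run_start = seg_begin
                    if run_start is not None:
                        calls.append(
                            _make_call(record, seq, strand, frame, codons,
                                       run_start, i + 1, has_stop=True,
                                       min_len=min_len, require_start=require_start)
                        )
                    run_start = None
                    seg_begin = i + 1
                elif at_end:
                    if run_start is None and not require_start and seg_begin < n_codons:
                        run_start = seg_begin
                    if run_start is not None and run_start < n_codons:
                        calls.append(
                            _make_call(record, seq, strand, frame, codons,
                                       run_start, n_codons, has_stop=False,
                                       min_len=min_len, require_start=require_start)
                        )
                elif codon == "ATG" and run_start is None and require_start:
                    run_start = i
                i += 1
    return [c for c in calls if c is not None]


def _make_call(
    record: TranscriptRecord,
    strand_seq: str,
    strand: str,
    frame: int,
    codons: list[str],
    c_start: int,
    c_end: int,
    has_stop: bool,
    min_len: int,
    require_start: bool,
) -> OrfCall | None:
    nt_len = 3 * (c_end - c_start)
    if nt_len < min_len:
        return None
    L = len(record.seq)
    s = frame + 3 * c_start
    e = frame + 3 * c_end
    if strand == "+":
        start, end = s, e
    else:
        start, end = L - e, L - s
    coding = codons[c_start : c_end - 1] if has_stop else codons[c_start:c_end]
    has_start = codons[c_start] == "ATG"
    return OrfCall(
        transcript_id=record.id,
        start=start,
        end=end,
        strand=strand,
        frame=frame,
        has_start=has_start,
        has_stop=has_stop,
        peptide=translate(coding),
    )


def train_codon_table(cds_seqs: list[str], pseudocount: float = 1.0) -> CodonUsageTable:
    """Estimate a codon-usage table from in-frame CDS nucleotide sequences.

    A terminal stop codon, when present, is stripped; stop codons and
    codons containing ambiguous bases are excluded from counting.  Each
    sense codon receives ``pseudocount`` extra counts before normalizing.
    """
    counts = {c: 0 for c in SENSE_CODONS}
    n_codons = 0
    for seq in cds_seqs:
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS length {len(seq)} is not divisible by 3")
        if seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
                n_codons += 1
    total = n_codons + pseudocount * len(SENSE_CODONS)
    if total == 0:
        raise ValueError("untrainable: no codons and zero pseudocount")
    freq = {c: (counts[c] + pseudocount) / total for c in SENSE_CODONS}
    return CodonUsageTable(
        freq=freq, pseudocount=pseudocount, n_training_codons=n_codons
    )


def _background_vector(background: str, mono: dict[str, float] | None) -> dict[str, float]:
    if background == "uniform":
        return {c: 1.0 / 61.0 for c in SENSE_CODONS}
    if background == "transcript-mono":
        if mono is None:
            raise ValueError("transcript-mono background needs mononucleotide frequencies")
        floor = 1e-6
        f = {b: max(mono.get(b, 0.0), floor) for b in "ACGT"}
        raw = {c: f[c[0]] * f[c[1]] * f[c[2]] for c in SENSE_CODONS}
        total = sum(raw.values())
        return {c: v / total for c, v in raw.items()}
    raise ValueError(f"unknown background '{background}'")


def score_orf(
    codons: list[str],
    table: CodonUsageTable,
    background: str = "uniform",
    mono: dict[str, float] | None = None,
) -> float:
    """Log-likelihood ratio in bits of a codon list under table vs background.

    A terminal stop codon and any codon containing ambiguous bases are
    skipped.  Raises when the table assigns zero frequency to a codon being
    scored (train with a positive pseudocount).
    """
    b = _background_vector(background, mono)
    score = 0.0
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if i == len(codons) - 1:
                continue
            raise ValueError("internal stop codon in scored codon list")
        if codon not in b:
            continue  # ambiguous codon: skipped
        q = table.freq.get(codon, 0.0)
        if q == 0.0:
            raise ValueError(f"zero table frequency for {codon}: apply pseudocount")
        score += log2(q / b[codon])
    return score


def select_best_cds(candidates: list[OrfCall]) -> OrfCall | None:
    """Highest-scoring candidate with positive score, with deterministic ties.

    Ties break toward the longer call, then the smaller start, then the
    plus strand.  Returns ``None`` when no candidate scores above zero.
    """
    scored = [c for c in candidates if c.score is not None and c.score > 0]
    if not scored:
        return None
    return max(
        scored,
        key=lambda c: (c.score, c.length, -c.start, 1 if c.strand == "+" else 0),
    )


@dataclass
class IterationDiagnostics:
    iteration: int
    n_selected: int
    l1_change: float | None


def iterative_cds_prediction(
    records: list[TranscriptRecord],
    n_iter: int = 4,
    min_len: int = 300,
    pseudocount: float = 1.0,
    tol: float = 1e-4,
    background: str = "uniform",
    require_start: bool = True,
) -> tuple[dict[str, OrfCall], list[CodonUsageTable], list[IterationDiagnostics]]:
    """Self-training CDS prediction.

    Iteration 0 trains the codon table on the single longest candidate ORF
    of every transcript (a frame is needed before any usage can be
    counted).  Each subsequent iteration re-scores all candidates with the
    previous table, keeps the best-scoring CDS per transcript, and retrains
    on the kept set.  Stops after ``n_iter`` iterations or as soon as the
    table's L1 change drops below ``tol``.

    Returns the final per-transcript calls, the per-iteration tables
    (index = iteration), and per-iteration diagnostics.
    """
    if not records:
        raise ValueError("no records")
    seqs = {r.id: r.seq for r in records}
    candidates: dict[str, list[OrfCall]] = {}
    for rec in records:
        cands = find_candidate_orfs(rec, min_len=min_len, require_start=require_start)
        if cands:
            candidates[rec.id] = cands

    if not candidates:
        raise ValueError("no training material: no transcript yields a candidate ORF")

    mono_cache: dict[str, dict[str, float]] = {}
    if background == "transcript-mono":
        for tid in candidates:
            seq = seqs[tid]
            counts = {b: seq.count(b) for b in "ACGT"}
            total = sum(counts.values()) or 1
            mono_cache[tid] = {b: counts[b] / total for b in "ACGT"}

    # bootstrap: longest candidate per transcript, deterministic tie-break
    bootstrap = [
        max(cands, key=lambda c: (c.length, -c.start, 1 if c.strand == "+" else 0))
        for cands in candidates.values()
    ]
    table = train_codon_table(
        [c.nt_seq(seqs[c.transcript_id]) for c in bootstrap], pseudocount=pseudocount
    )
    tables = [replace(table, iteration=0)]
    diagnostics = [IterationDiagnostics(iteration=0, n_selected=len(bootstrap), l1_change=None)]

    selected: dict[str, OrfCall] = {}
    for k in range(1, n_iter + 1):
        prev = tables[-1]
        selected = {}
        for tid, cands in candidates.items():
            mono = mono_cache.get(tid)
            scored = [
                replace(
                    c,
                    score=score_orf(
                        c.codons(seqs[tid]), prev, background=background, mono=mono
                    ),
                )
                for c in cands
            ]
            best = select_best_cds(scored)
            if best is not None:
                selected[tid] = best
        if not selected:
            raise ValueError("no training material: no CDS selected")
        table = train_codon_table(
            [c.nt_seq(seqs[c.transcript_id]) for c in selected.values()],
            pseudocount=pseudocount,
        )
        table = replace(table, iteration=k)
        change = table.l1_distance(prev)
        tables.append(table)
        diagnostics.append(
            IterationDiagnostics(iteration=k, n_selected=len(selected), l1_change=change)
        )
        if change < tol:
            break
    return selected, tables, diagnostics
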
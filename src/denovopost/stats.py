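"""Assembly summary statistics and annotation-coverage reporting.

N50 is the standard contiguity statistic for an assembly: the length L
such that transcripts of length >= L cover at least half the assembled
bases.  GC content is aggregated over all transcripts with ambiguous bases
excluded.  Annotation coverage is reported as percentages of the total
transcript count, rounded half-away-from-zero to a per-category precision
(whole percent for large categories, one decimal for rare ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .io import TranscriptRecord


@dataclass(frozen=True)
class AssemblyStats:
    n_transcripts: int
    n_genes: int
    n50: int
    mean_length: float
    gc_percent: float
    histogram_edges: tuple[int, ...]
    histogram_counts: tuple[int, ...]


@dataclass(frozen=True)
class AnnotationSummary:
    n_total: int
    counts: dict[str, int]
    percentages: dict[str, float]


def n50(lengths: list[int]) -> int:
    """Smallest length among the longest transcripts covering half the bases."""
    if not lengths:
        raise ValueError("n50 of an empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def gc_percent(records: list[TranscriptRecord]) -> float:
    """Aggregate GC% over all records; N excluded from both terms."""
    if not records:
        raise ValueError("gc_percent of an empty record list")
    gc = 0
    acgt = 0
    for rec in records:
        seq = rec.seq.upper()
        g = seq.count("G") + seq.count("C")
        gc += g
        acgt += g + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * gc / acgt


def length_histogram(
    records: list[TranscriptRecord], bin_edges: list[int]
) -> list[int]:
    """Counts per half-open bin [e_i, e_{i+1}); final overflow bin >= last edge."""
    if not bin_edges or any(b <= a for a, b in zip(bin_edges, bin_edges[1:])):
        raise ValueError("bin edges must be strictly increasing and non-empty")
    lengths = [len(r.seq) for r in records]
    counts = [0] * len(bin_edges)
    for L in lengths:
        placed = False
        for i in range(len(bin_edges) - 1):
            if bin_edges[i] <= L < bin_edges[i + 1]:
                counts[i] += 1
                placed = True
                break
        if not placed and L >= bin_edges[-1]:
            counts[-1] += 1
    return counts


def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def annotation_summary(
    n_total: int,
    categories: dict[str, int],
    rounding: dict[str, int] | int = 0,
) -> AnnotationSummary:
    """Percent coverage per annotation category.

    ``rounding`` is either a single decimal precision for every category or
    a per-category map.  Percentages are 100 * count / n_total rounded
    half-away-from-zero.  A count exceeding ``n_total`` is rejected.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    percentages = {}
    for name, count in categories.items():
        if count > n_total:
            raise ValueError(f"category '{name}' count {count} exceeds total {n_total}")
        if count < 0:
            raise ValueError(f"negative count for '{name}'")
        nd = rounding.get(name, 0) if isinstance(rounding, dict) else rounding
        percentages[name] = round_half_away(100.0 * count / n_total, nd)
    return AnnotationSummary(n_total=n_total, counts=dict(categories), percentages=percentages)


def assembly_stats(
    records: list[TranscriptRecord],
    n_genes: int | None = None,
    bin_edges: list[int] | None = None,
) -> AssemblyStats:
    """Full summary for a transcript set (N50, mean length, GC%, histogram)."""
    if not records:
        raise ValueError("no records")
    lengths = [len(r.seq) for r in records]
    edges = bin_edges if bin_edges is not None else [0, 500, 1000, 2000, 4000, 8000]
    from .expression import group_transcripts_to_genes

    if n_genes is None:
        n_genes = len(group_transcripts_to_genes([r.id for r in records]))
    return AssemblyStats(
        n_transcripts=len(records),
        n_genes=n_genes,
        n50=n50(lengths),
        mean_length=round(float(np.mean(lengths)), 2),
        gc_percent=round(gc_percent(records), 2),
        histogram_edges=tuple(edges),
        histogram_counts=tuple(length_histogram(records, edges)),
    )
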
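"""Contaminant screening by dinucleotide relative abundance.

Assembled transcript sets from a single organism share a compositional
"genome signature": the strand-symmetrized dinucleotide relative abundances
rho*_XY = f_XY / (f_X * f_Y).  Sequences assembled from co-cultured or
contaminating organisms tend to sit far from the pooled signature of the
assembly, so compositional outliers can be flagged without any reference
database.  Distance between two signatures is the average absolute
difference of their sixteen rho* values, scaled to per-mille units:

    delta(f, g) = (1000 / 16) * sum_XY | rho_f(XY) - rho_g(XY) |

Flagging uses a robust threshold, median(delta) + k * MAD(delta), or an
absolute per-mille cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import TranscriptRecord

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
# complement index: A<->T, C<->G
_COMP = np.array([3, 2, 1, 0])

DINUCLEOTIDES = [x + y for x in _BASES for y in _BASES]


@dataclass(frozen=True)
class DinucleotideSignature:
    """Strand-symmetrized mono- and dinucleotide relative-abundance profile.

    ``mono`` holds the four base frequencies (A, C, G, T order; sums to 1)
    and ``rho`` the 4x4 matrix of relative abundances rho*_XY.  Both are
    computed from a sequence pooled with its reverse complement, which makes
    the profile independent of assembly strand: rho_XY == rho_rc(Y)rc(X)
    exactly.
    """

    mono: np.ndarray
    rho: np.ndarray
    n_dinucs_counted: int

    def rho_of(self, dinuc: str) -> float:
        return float(self.rho[_CODE[dinuc[0]], _CODE[dinuc[1]]])

    def mono_of(self, base: str) -> float:
        return float(self.mono[_CODE[base]])


@dataclass
class ScreenReport:
    """Outcome of a contaminant screen over one transcript set."""

    deltas: dict[str, float]
    flagged: list[str]
    threshold: float
    pooled: DinucleotideSignature
    eligible_ids: list[str]
    exempt_ids: list[str] = field(default_factory=list)


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3, ambiguous bases to -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _CODE.items():
        codes[arr == ord(base)] = idx
    return codes


def _count_seq(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand mono (len-4) and dinucleotide (4x4) counts.

    Overlapping dinucleotides, no wraparound; any pair touching an
    ambiguous base is skipped, and ambiguous bases are excluded from the
    mono counts.
    """
    codes = _encode(seq)
    valid = codes >= 0
    mono = np.bincount(codes[valid], minlength=4).astype(np.int64)
    if len(codes) >= 2:
        a, b = codes[:-1], codes[1:]
        keep = (a >= 0) & (b >= 0)
        dinuc = np.bincount(a[keep] * 4 + b[keep], minlength=16).reshape(4, 4)
    else:
        dinuc = np.zeros((4, 4), dtype=np.int64)
    return mono, dinuc.astype(np.int64)


def _symmetrize(mono: np.ndarray, dinuc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pool forward-strand counts with their reverse-complement image."""
    mono_sym = mono + mono[_COMP]
    # count of XY on the reverse complement equals count of rc(Y)rc(X) forward
    dinuc_sym = dinuc + dinuc[np.ix_(_COMP, _COMP)].T
    return mono_sym, dinuc_sym


def _signature_from_counts(mono: np.ndarray, dinuc: np.ndarray) -> DinucleotideSignature:
    mono_sym, dinuc_sym = _symmetrize(mono, dinuc)
    n_dinucs = int(dinuc_sym.sum())
    if n_dinucs == 0 or mono_sym.sum() == 0:
        raise ValueError("uninformative sequence: no unambiguous dinucleotides")
    f_mono = mono_sym / mono_sym.sum()
    f_dinuc = dinuc_sym / n_dinucs
    denom = np.outer(f_mono, f_mono)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, f_dinuc / np.where(denom > 0, denom, 1.0), 0.0)
    return DinucleotideSignature(mono=f_mono, rho=rho, n_dinucs_counted=n_dinucs)


def dinucleotide_signature(seq: str) -> DinucleotideSignature:
    """Signature of a single sequence (pooled with its reverse complement)."""
    return _signature_from_counts(*_count_seq(seq))


def pooled_signature(seqs: list[str]) -> DinucleotideSignature:
    """Signature of a pool of sequences; counts are summed before normalizing."""
    mono = np.zeros(4, dtype=np.int64)
    dinuc = np.zeros((4, 4), dtype=np.int64)
    for seq in seqs:
        m, d = _count_seq(seq)
        mono += m
        dinuc += d
    return _signature_from_counts(mono, dinuc)


def delta_distance(f: DinucleotideSignature, g: DinucleotideSignature) -> float:
    """Per-mille signature distance: (1000/16) * sum |rho_f - rho_g|."""
    return float(1000.0 / 16.0 * np.abs(f.rho - g.rho).sum())


def screen_contaminants(
    records: list[TranscriptRecord],
    min_len: int = 500,
    mad_k: float | None = 5.0,
    absolute_cutoff: float | None = None,
) -> ScreenReport:
    """Flag compositional outliers against the pooled assembly signature.

    Transcripts shorter than ``min_len`` are exempt from flagging (their
    signatures are too noisy) and do not enter the pool.  The threshold is
    ``median(delta) + mad_k * MAD(delta)`` unless ``absolute_cutoff``
    (per-mille) is given, which takes precedence.

    Raises ``ValueError`` when fewer than two eligible records exist.
    """
    eligible = [r for r in records if len(r.seq) >= min_len]
    exempt = [r.id for r in records if len(r.seq) < min_len]
    if len(eligible) < 2:
        raise ValueError(
            f"insufficient data: need >= 2 records of length >= {min_len}, "
            f"got {len(eligible)}"
        )
    pool = pooled_signature([r.seq for r in eligible])
    # deterministic order for the report; decisions are order-independent
    deltas = {r.id: delta_distance(dinucleotide_signature(r.seq), pool) for r in eligible}
    values = np.array([deltas[r.id] for r in eligible])
    if absolute_cutoff is not None:
        threshold = float(absolute_cutoff)
    else:
        if mad_k is None:
            raise ValueError("one of mad_k or absolute_cutoff must be given")
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        threshold = med + mad_k * mad
    flagged = sorted([r.id for r in eligible if deltas[r.id] > threshold])
    return ScreenReport(
        deltas=deltas,
        flagged=flagged,
        threshold=threshold,
        pooled=pool,
        eligible_ids=[r.id for r in eligible],
        exempt_ids=exempt,
    )
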
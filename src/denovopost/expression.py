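"""FPKM quantification and fold-change differential expression.

With one sequencing library per condition there is no replication to
estimate within-group variance, so differential expression is called
purely by effect size: a transcript is DE when its |log2 fold change| of
FPKM between treated and control reaches a threshold (default 1, i.e.
two-fold).  Isoforms are grouped to genes by their Trinity-style
identifiers (``compX_cY_seqZ`` -> gene ``compX_cY``), and a gene is DE when
any of its isoforms is.

FPKM = count * 1e9 / (length * total_mapped); a small FPKM pseudocount
stabilizes fold changes when one condition is near zero.  A ``2^-ddCt``
helper converts qPCR cycle thresholds, normalized to a reference gene, to
relative fold change.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import log2

import pandas as pd

TRINITY_ID = re.compile(r"^(comp\d+_c\d+)_seq\d+$")


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    length: int
    count_control: int
    count_treated: int
    fpkm_control: float
    fpkm_treated: float
    log2fc: float
    de_status: str  # up | down | none


@dataclass
class GeneGroup:
    gene_id: str
    members: list[str]
    de_status: str = "none"


def compute_fpkm(count: float, length: int, total_mapped: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if length <= 0:
        raise ValueError(f"non-positive transcript length {length}")
    if total_mapped <= 0:
        raise ValueError(f"non-positive library size {total_mapped}")
    return count * 1e9 / (length * total_mapped)


def log2_fold_change(fpkm_treated: float, fpkm_control: float, pseudo: float = 0.01) -> float:
    """log2((treated + pseudo) / (control + pseudo)); finite for all inputs."""
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    return log2((fpkm_treated + pseudo) / (fpkm_control + pseudo))


def call_de(log2fc: float, threshold: float = 1.0) -> str:
    """DE status at a log2 threshold; boundaries are inclusive."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if log2fc >= threshold:
        return "up"
    if log2fc <= -threshold:
        return "down"
    return "none"


def group_transcripts_to_genes(ids: list[str]) -> list[GeneGroup]:
    """Group isoform ids to genes by the ``compX_cY_seqZ`` convention.

    Non-matching ids become singleton genes under their own id.  The result
    is sorted by gene id, hence independent of input order.
    """
    members: dict[str, list[str]] = {}
    for tid in ids:
        m = TRINITY_ID.match(tid)
        gene = m.group(1) if m else tid
        members.setdefault(gene, []).append(tid)
    return [GeneGroup(gene_id=g, members=sorted(ms)) for g, ms in sorted(members.items())]


def quantify(
    counts: pd.DataFrame,
    pseudo: float = 0.01,
    threshold: float = 1.0,
    min_count: int = 1,
    total_control: float | None = None,
    total_treated: float | None = None,
) -> pd.DataFrame:
    """Per-transcript FPKM, log2 fold change, and DE status.

    ``counts`` needs columns transcript_id, length, count_control,
    count_treated.  Library sizes (total mapped fragments) default to the
    column totals; pass ``total_control``/``total_treated`` when the true
    library depths are known — total mapped fragments is a property of the
    library, not of whichever transcript subset is being quantified.
    Transcripts with fewer than ``min_count`` fragments in both conditions
    are never called DE (guards fold changes computed from noise).
    """
    if counts.empty:
        return pd.DataFrame(
            columns=[
                "transcript_id", "gene_id", "length", "count_control",
                "count_treated", "fpkm_control", "fpkm_treated", "log2fc",
                "de_status",
            ]
        )
    if total_control is None:
        total_control = float(counts["count_control"].sum())
    if total_treated is None:
        total_treated = float(counts["count_treated"].sum())
    rows = []
    for row in counts.itertuples(index=False):
        fpkm_c = compute_fpkm(row.count_control, row.length, total_control)
        fpkm_t = compute_fpkm(row.count_treated, row.length, total_treated)
        lfc = log2_fold_change(fpkm_t, fpkm_c, pseudo=pseudo)
        status = call_de(lfc, threshold=threshold)
        if max(row.count_control, row.count_treated) < min_count:
            status = "none"
        m = TRINITY_ID.match(row.transcript_id)
        rows.append(
            {
                "transcript_id": row.transcript_id,
                "gene_id": m.group(1) if m else row.transcript_id,
                "length": row.length,
                "count_control": row.count_control,
                "count_treated": row.count_treated,
                "fpkm_control": fpkm_c,
                "fpkm_treated": fpkm_t,
                "log2fc": lfc,
                "de_status": status,
            }
        )
    return pd.DataFrame(rows)


def gene_level_de(
    records: pd.DataFrame, groups: list[GeneGroup] | None = None
) -> tuple[list[GeneGroup], dict[str, int]]:
    """Gene DE status (any-isoform rule) plus transcript/gene tallies.

    ``records`` is the table from :func:`quantify`.  Raises when a group
    member has no expression record.
    """
    status = dict(zip(records["transcript_id"], records["de_status"]))
    if groups is None:
        groups = group_transcripts_to_genes(list(records["transcript_id"]))
    for g in groups:
        missing = [m for m in g.members if m not in status]
        if missing:
            raise ValueError(f"missing expression record for '{missing[0]}'")
        member_status = {status[m] for m in g.members}
        if "up" in member_status and "down" in member_status:
            g.de_status = "mixed"
        elif "up" in member_status:
            g.de_status = "up"
        elif "down" in member_status:
            g.de_status = "down"
        else:
            g.de_status = "none"
    n_up = int((records["de_status"] == "up").sum())
    n_down = int((records["de_status"] == "down").sum())
    tallies = {
        "n_transcripts": len(records),
        "n_genes": len(groups),
        "n_de_transcripts": n_up + n_down,
        "n_up": n_up,
        "n_down": n_down,
        "n_de_genes": sum(1 for g in groups if g.de_status != "none"),
    }
    return groups, tallies


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method with a reference gene."""
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)
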
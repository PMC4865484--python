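"""End-to-end pipeline: screen -> CDS prediction -> quantification -> stats.

One configuration object drives a reproducible run over a FASTA of
assembled transcripts and a two-condition count table.  Stages run in the
order a post-assembly analysis does — contaminant screening first (flagged
transcripts are dropped from everything downstream), then iterative
codon-preference CDS prediction, FPKM fold-change differential expression,
and assembly summary statistics.  A manifest JSON records parameters,
per-stage record counts and output files; rerunning with the same
configuration and inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .expression import gene_level_de, quantify
from .io import TranscriptRecord, read_counts, read_fasta, write_fasta
from .orf import iterative_cds_prediction
from .screen import screen_contaminants
from .stats import assembly_stats

logger = logging.getLogger("denovopost")

DEFAULT_BIN_EDGES = [0, 500, 1000, 2000, 4000, 8000]


@dataclass
class PipelineConfig:
    """Flat, file-serializable configuration for one pipeline run."""

    seed: int = 0
    # screening
    screen_min_len: int = 500
    screen_mad_k: float = 5.0
    screen_absolute_cutoff: float | None = None
    # ORF calling
    orf_n_iter: int = 4
    orf_min_len: int = 300
    orf_pseudocount: float = 1.0
    orf_background: str = "uniform"
    orf_tol: float = 1e-4
    # expression
    expr_pseudo: float = 0.01
    expr_log2fc_threshold: float = 1.0
    expr_min_count: int = 1
    # stats
    stats_bin_edges: list[int] = field(default_factory=lambda: list(DEFAULT_BIN_EDGES))
    outdir: str = "denovopost_out"

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if isinstance(value, list):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{f.name} = {value}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            text = raw[f.name]
            if text == "None":
                kwargs[f.name] = None
            elif f.name == "stats_bin_edges":
                kwargs[f.name] = [int(x) for x in text.split(",") if x]
            elif f.type in ("int",):
                kwargs[f.name] = int(text)
            elif f.type in ("float", "float | None"):
                kwargs[f.name] = float(text)
            elif f.type == "str":
                kwargs[f.name] = text
            else:
                kwargs[f.name] = text
        return cls(**kwargs)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds expanded from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(4)
        names = ["simulate", "screen", "orf", "expression"]
        return {
            name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for name, child in zip(names, children)
        }


def write_orf_outputs(selected, seqs: dict[str, str], outdir: Path) -> None:
    """Write CDS FASTA, peptide FASTA and BED6 for a set of ORF calls."""
    calls = sorted(selected.values(), key=lambda c: c.transcript_id)
    cds_records = [TranscriptRecord(c.transcript_id, c.nt_seq(seqs[c.transcript_id])) for c in calls]
    pep_records = [TranscriptRecord(c.transcript_id, c.peptide) for c in calls]
    write_fasta(cds_records, outdir / "cds.fa")
    write_fasta(pep_records, outdir / "pep.fa")
    with open(outdir / "orfs.bed", "w") as fh:
        for c in calls:
            score = 0.0 if c.score is None else round(c.score, 2)
            fh.write(f"{c.transcript_id}\t{c.start}\t{c.end}\t{c.transcript_id}_cds\t{score}\t{c.strand}\n")


def run_all(config: PipelineConfig, fasta: str | Path, counts: str | Path) -> Path:
    """Run every stage; returns the output directory.

    Any stage failure aborts with the stage name in the message; the
    manifest marks the run incomplete in that case.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {f.name: getattr(config, f.name) for f in dataclasses.fields(config)},
        "stage_seeds": config.stage_seeds(),
        "inputs": {"fasta": str(fasta), "counts": str(counts)},
        "complete": False,
        "counts": {},
        "warnings": [],
    }
    config.to_file(outdir / "config.txt")

    def _fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    try:
        records = read_fasta(fasta)
        if not records:
            raise ValueError("empty FASTA: nothing to process")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'read' failed: {exc}") from exc
    manifest["counts"]["transcripts_in"] = len(records)

    # --- screen ---
    try:
        report = screen_contaminants(
            records,
            min_len=config.screen_min_len,
            mad_k=config.screen_mad_k,
            absolute_cutoff=config.screen_absolute_cutoff,
        )
    except Exception as exc:
        _fail("screen", exc)
    flagged = set(report.flagged)
    retained = [r for r in records if r.id not in flagged]
    if report.exempt_ids:
        manifest["warnings"].append(
            f"{len(report.exempt_ids)} transcripts shorter than {config.screen_min_len} nt "
            "were exempt from contaminant screening"
        )
    manifest["counts"]["flagged"] = len(flagged)
    manifest["counts"]["retained"] = len(retained)
    with open(outdir / "flagged.txt", "w") as fh:
        fh.writelines(f"{tid}\n" for tid in sorted(flagged))
    with open(outdir / "screen_report.tsv", "w") as fh:
        fh.write("id\tlength\tdelta_permille\tflagged\n")
        lengths = {r.id: len(r.seq) for r in records}
        for tid in report.eligible_ids:
            fh.write(f"{tid}\t{lengths[tid]}\t{report.deltas[tid]:.3f}\t{tid in flagged}\n")
    write_fasta(retained, outdir / "filtered.fa")
    logger.info("screen: %d flagged of %d", len(flagged), len(records))

    # --- ORF calling ---
    try:
        selected, tables, diags = iterative_cds_prediction(
            retained,
            n_iter=config.orf_n_iter,
            min_len=config.orf_min_len,
            pseudocount=config.orf_pseudocount,
            tol=config.orf_tol,
            background=config.orf_background,
        )
    except Exception as exc:
        _fail("orfcall", exc)
    seqs = {r.id: r.seq for r in retained}
    write_orf_outputs(selected, seqs, outdir)
    with open(outdir / "tables.tsv", "w") as fh:
        fh.write("codon\tfrequency\titeration\n")
        for table in tables:
            for codon in sorted(table.freq):
                fh.write(f"{codon}\t{table.freq[codon]:.6g}\t{table.iteration}\n")
    manifest["counts"]["cds_called"] = len(selected)
    manifest["orf_iterations"] = [
        {"iteration": d.iteration, "n_selected": d.n_selected, "l1_change": d.l1_change}
        for d in diags
    ]
    logger.info("orfcall: %d CDS after %d iterations", len(selected), diags[-1].iteration)

    # --- expression / DE ---
    try:
        counts_table = read_counts(counts)
        counts_table = counts_table[counts_table["transcript_id"].isin(seqs)].reset_index(drop=True)
        expr = quantify(
            counts_table,
            pseudo=config.expr_pseudo,
            threshold=config.expr_log2fc_threshold,
            min_count=config.expr_min_count,
        )
        groups, tallies = gene_level_de(expr)
    except Exception as exc:
        _fail("quant", exc)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False, float_format="%.6g")
    with open(outdir / "de_summary.json", "w") as fh:
        json.dump(tallies, fh, indent=2)
    manifest["counts"].update(tallies)

    # --- stats ---
    try:
        stats = assembly_stats(retained, bin_edges=config.stats_bin_edges)
    except Exception as exc:
        _fail("stats", exc)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(dataclasses.asdict(stats), fh, indent=2)

    manifest["complete"] = True
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
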
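"""Codon-preference CDS prediction: ORF enumeration, scoring, self-training."""

from math import log2

import numpy as np
import pytest

import denovopost as dp
from denovopost.io import revcomp
from denovopost.orf import SENSE_CODONS, STOP_CODONS

from .conftest import reading_frame


# ---------------------------------------------------------------------------
# independent brute-force oracle for ORF enumeration
# ---------------------------------------------------------------------------

def brute_force_orfs(seq, min_len, require_start=True, both_strands=True):
    """Enumerate maximal start-to-stop runs by scanning every frame position."""
    found = set()
    L = len(seq)
    for strand in ("+", "-") if both_strands else ("+",):
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            n = (L - frame) // 3
            codons = [s[frame + 3 * i : frame + 3 * i + 3] for i in range(n)]
            i = 0
            while i < n:
                # candidate run start: first ATG (or segment start) after a stop
                if require_start:
                    if codons[i] != "ATG":
                        i += 1
                        continue
                # extend to next stop or frame end
                j = i
                while j < n and codons[j] not in STOP_CODONS:
                    j += 1
                has_stop = j < n
                end_codon = j + 1 if has_stop else j
                nt_len = 3 * (end_codon - i)
                if nt_len >= min_len:
                    a, b = frame + 3 * i, frame + 3 * end_codon
                    if strand == "-":
                        a, b = L - b, L - a
                    found.add((a, b, strand, frame, has_stop))
                # skip to after this stop; only the first start per segment counts
                i = end_codon if has_stop else n
            if not require_start:
                # segment starts are after stops or the frame origin
                found_open = set()
                seg = 0
                k = 0
                while k <= n:
                    if k == n or codons[k] in STOP_CODONS:
                        has_stop = k < n
                        end_codon = k + 1 if has_stop else k
                        nt_len = 3 * (end_codon - seg)
                        if nt_len >= min_len and end_codon > seg:
                            a, b = frame + 3 * seg, frame + 3 * end_codon
                            if strand == "-":
                                a, b = L - b, L - a
                            found_open.add((a, b, strand, frame, has_stop))
                        seg = k + 1
                    k += 1
                found |= found_open
    return found


def as_tuples(calls):
    return {(c.start, c.end, c.strand, c.frame, c.has_stop) for c in calls}


def test_single_orf_hand_example():
    calls = dp.find_candidate_orfs(dp.TranscriptRecord("t", "ATGAAATAG"), min_len=9)
    plus = [c for c in calls if c.strand == "+"]
    assert len(plus) == 1
    call = plus[0]
    assert (call.start, call.end, call.strand) == (0, 9, "+")
    assert call.peptide == "MK"
    assert call.has_start and call.has_stop


def test_no_atg_means_no_calls():
    rec = dp.TranscriptRecord("t", "CCCCCCCCCCCCCCC")
    assert dp.find_candidate_orfs(rec, min_len=3) == []


@pytest.mark.parametrize("require_start", [True, False])
def test_orf_finder_matches_brute_force(rng, require_start):
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        rec = dp.TranscriptRecord("t", seq)
        calls = dp.find_candidate_orfs(rec, min_len=30, require_start=require_start)
        assert as_tuples(calls) == brute_force_orfs(seq, 30, require_start=require_start)


def test_minus_strand_coordinates_mirror():
    """Calling on the reverse complement swaps strands and mirrors coordinates."""
    records, _ = dp.generate_host_transcripts(20, seed=21)
    for rec in records:
        fwd = dp.find_candidate_orfs(rec, min_len=150)
        rc = dp.find_candidate_orfs(dp.TranscriptRecord(rec.id, revcomp(rec.seq)), min_len=150)
        L = len(rec.seq)
        mirrored = {
            (L - c.end, L - c.start, "+" if c.strand == "-" else "-", c.frame, c.has_stop)
            for c in rc
        }
        assert as_tuples(fwd) == mirrored


class TestTraining:
    def test_two_codon_table(self):
        table = dp.train_codon_table(["ATGAAA"], pseudocount=0)
        assert table.freq["ATG"] == pytest.approx(0.5)
        assert table.freq["AAA"] == pytest.approx(0.5)
        assert sum(v for v in table.freq.values()) == pytest.approx(1.0)

    def test_terminal_stop_stripped(self):
        with_stop = dp.train_codon_table(["ATGAAATAA"], pseudocount=0)
        without = dp.train_codon_table(["ATGAAA"], pseudocount=0)
        assert with_stop.freq == without.freq

    def test_untrainable(self):
        with pytest.raises(ValueError, match="untrainable"):
            dp.train_codon_table([], pseudocount=0)

    def test_pseudocount_makes_all_positive(self):
        table = dp.train_codon_table(["ATGAAA"], pseudocount=1.0)
        assert all(v > 0 for v in table.freq.values())

    def test_recovers_generator_table(self, host_set, skewed_table):
        records, truth = host_set
        cds = [
            rec.seq[t.orf_start : t.orf_end] if t.orf_strand == "+"
            else revcomp(rec.seq[t.orf_start : t.orf_end])
            for rec, t in ((r, truth.records[r.id]) for r in records)
        ]
        table = dp.train_codon_table(cds, pseudocount=1.0)
        assert table.tv_distance(skewed_table) <= 0.05


class TestScoring:
    def test_score_zero_when_table_equals_background(self):
        assert dp.score_orf(["ATG", "AAA"], dp.uniform_table()) == pytest.approx(0.0)

    def test_hand_score(self):
        table = dp.CodonUsageTable(freq={"ATG": 0.5, "AAA": 0.5})
        score = dp.score_orf(["ATG", "AAA"], table)
        assert score == pytest.approx(2 * log2(0.5 * 61))
        assert score == pytest.approx(9.861, abs=5e-4)

    def test_additivity(self, skewed_table, rng):
        a = list(rng.choice(SENSE_CODONS, size=10))
        b = list(rng.choice(SENSE_CODONS, size=7))
        total = dp.score_orf(a + b, skewed_table)
        assert total == pytest.approx(dp.score_orf(a, skewed_table) + dp.score_orf(b, skewed_table))

    def test_zero_frequency_rejected(self):
        table = dp.CodonUsageTable(freq={"ATG": 1.0})
        with pytest.raises(ValueError, match="pseudocount"):
            dp.score_orf(["AAA"], table)


class TestSelection:
    def _call(self, score, start=0, length=300, strand="+"):
        return dp.OrfCall("t", start, start + length, strand, 0, True, True, "M", score=score)

    def test_empty_and_all_nonpositive(self):
        assert dp.select_best_cds([]) is None
        assert dp.select_best_cds([self._call(-1.0), self._call(0.0)]) is None

    def test_highest_score_wins(self):
        a, b = self._call(5.0), self._call(3.0)
        assert dp.select_best_cds([a, b]) is a

    def test_tie_breaks(self):
        short = self._call(5.0, length=300)
        long = self._call(5.0, start=10, length=600)
        assert dp.select_best_cds([short, long]) is long
        early = self._call(5.0, start=0)
        late = self._call(5.0, start=30)
        assert dp.select_best_cds([early, late]) is early
        minus = self._call(5.0, strand="-")
        plus = self._call(5.0, strand="+")
        assert dp.select_best_cds([minus, plus]) is plus


class TestIteration:
    def test_pure_orfs_reach_fixed_point_immediately(self, skewed_table):
        """Transcripts that are bare planted ORFs train to a fixed point."""
        records, _ = dp.generate_host_transcripts(
            100, utr_len_range=(0, 0), seed=30
        )
        selected, tables, diags = dp.iterative_cds_prediction(records, n_iter=4)
        changes = [d.l1_change for d in diags[1:]]
        assert changes[-1] < 1e-4  # early stop at the fixed point
        assert len(tables) <= 3

    def test_single_iteration_equals_manual_round(self, host_set):
        records, _ = host_set
        records = records[:50]
        selected, tables, _ = dp.iterative_cds_prediction(records, n_iter=1)
        # manual: bootstrap on longest candidates, score, select
        seqs = {r.id: r.seq for r in records}
        cands = {r.id: dp.find_candidate_orfs(r) for r in records}
        cands = {k: v for k, v in cands.items() if v}
        longest = [
            max(v, key=lambda c: (c.length, -c.start, 1 if c.strand == "+" else 0))
            for v in cands.values()
        ]
        table0 = dp.train_codon_table([c.nt_seq(seqs[c.transcript_id]) for c in longest])
        manual = {}
        for tid, v in cands.items():
            scored = [
                dp.OrfCall(**{**c.__dict__, "score": dp.score_orf(c.codons(seqs[tid]), table0)})
                for c in v
            ]
            best = dp.select_best_cds(scored)
            if best:
                manual[tid] = (best.start, best.end, best.strand)
        assert {k: (c.start, c.end, c.strand) for k, c in selected.items()} == manual
        assert np.allclose(tables[0].as_vector(), table0.as_vector())

    def test_l1_change_recorded_and_shrinking(self, cds_run):
        _, tables, diags = cds_run
        changes = [d.l1_change for d in diags if d.l1_change is not None]
        assert all(c >= 0 for c in changes)
        assert changes == sorted(changes, reverse=True)

    def test_planted_frame_accuracy(self, cds_run, host_set):
        """Final-iteration calls identify the planted frame on >= 95% of
        coding transcripts, and iterating does not hurt."""
        records, truth = host_set
        selected, tables, _ = cds_run

        def accuracy(calls):
            hit = 0
            for rec in records:
                t = truth.records[rec.id]
                c = calls.get(rec.id)
                if c is None:
                    continue
                same_frame = reading_frame(c.start, c.end, c.strand, len(rec.seq)) == \
                    reading_frame(t.orf_start, t.orf_end, t.orf_strand, len(rec.seq))
                overlaps = min(c.end, t.orf_end) - max(c.start, t.orf_start) > 0
                hit += c.strand == t.orf_strand and same_frame and overlaps
            return hit / len(records)

        decoys_included = records + dp.generate_contaminants(
            200, model=dp.HOST_CHAIN, len_range=(400, 1300), seed=4, id_prefix="decoy"
        )[0]
        one_iter, _, _ = dp.iterative_cds_prediction(decoys_included, n_iter=1)
        final_acc = accuracy(selected)
        assert final_acc >= 0.95
        assert final_acc >= accuracy(one_iter)

    def test_trained_table_recovers_truth(self, cds_run, skewed_table):
        _, tables, _ = cds_run
        assert skewed_table.tv_distance(dp.uniform_table()) >= 0.3
        assert tables[-1].tv_distance(skewed_table) <= 0.1

    def test_no_candidates_raises(self):
        records = [dp.TranscriptRecord("t", "CCCCCC")]
        with pytest.raises(ValueError, match="no training material"):
            dp.iterative_cds_prediction(records)
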
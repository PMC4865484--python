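# Methods

This note documents the models and procedures implemented in `denovopost`,
the parameter choices that matter, and what the synthetic-data tests do and
do not demonstrate.

## Dinucleotide-signature contaminant screen

A sequence's compositional signature is the vector of dinucleotide relative
abundances ρ\*_XY = f_XY / (f_X · f_Y), computed after pooling the sequence
with its reverse complement (assembled transcripts have arbitrary strand, so
only the strand-symmetrized form is meaningful; the symmetry ρ_XY =
ρ_rc(Y)rc(X) then holds exactly by construction). Overlapping dinucleotides
are counted within each strand separately with no wraparound; a dinucleotide
touching an ambiguous base is skipped, and ambiguous bases are excluded from
the mononucleotide counts. ρ_XY is defined as 0 when f_X·f_Y = 0. For an
i.i.d. sequence all ρ_XY → 1 as length grows; the test suite checks the
band [0.95, 1.05] at length 10⁵.

Signature distance is δ(f,g) = (1000/16) Σ_XY |ρ_f − ρ_g| (per-mille). It
is a proper metric on signature space (symmetry, identity of
indiscernibles, triangle inequality — property-tested on random
signatures).

**Screening policy.** Transcripts of length ≥ `min_len` (default 500 nt;
shorter signatures are too noisy and are exempt from flagging) contribute
to a pooled assembly signature; each is flagged when its δ to the pool
exceeds median(δ) + `mad_k`·MAD(δ) with `mad_k` = 5 (MAD unscaled). The
robust default is used because any fixed per-mille cutoff is
dataset-dependent; an absolute cutoff override exists for calibrated use.
Screening is against the pooled self-signature, not against reference
signatures of suspect taxa; the latter would need external data and is left
as an extension point.

## Codon-preference CDS prediction

**Candidate enumeration.** For each of up to six frames, maximal runs from
the first ATG after the previous stop (optionally from the segment start
when `require_start=false`) to the next in-frame stop, stop codon included;
a trailing run without a stop is kept with `has_stop=false`. Runs shorter
than `min_len` = 300 nt (100 aa, a conventional floor for de novo calls)
are dropped. Coordinates are 0-based half-open on the forward strand
throughout; minus-strand calls carry `strand='-'` with mirrored
coordinates. The enumeration is verified exactly against a brute-force
position scan on random sequences.

**Scoring.** score = Σ_c log₂(q_c / b_c) bits over the sense codons of the
candidate (terminal stop and ambiguous codons skipped). Backgrounds: the
default `uniform` (b_c = 1/61) — under it a random codon sequence scores
negative in expectation (−KL in the wrong direction), so the "score > 0"
selection rule rejects most non-coding decoys; and `transcript-mono`, where
b_c is the product of the transcript's mononucleotide frequencies
renormalized over the 61 sense codons (base frequencies floored at 10⁻⁶ to
keep the background finite). Both are implemented; uniform is the default
because it needs no per-transcript estimate and performed identically on
synthetic data.

**Self-training.** Iteration 0 trains the codon table on the single
longest candidate ORF per transcript — raw transcripts include UTRs, and
codon counting needs a frame, so some bootstrap convention is unavoidable;
the longest-ORF choice is the standard one. Iterations k ≥ 1 re-score all
candidates with the previous table, keep the best-scoring CDS per
transcript (ties: longer, then smaller start, then plus strand; none when
no candidate scores above 0), and retrain on the kept set with an add-one
pseudocount per sense codon (avoids −∞ scores). Default `n_iter` = 4;
a tolerance (`tol` = 10⁻⁴ on the table's L1 change) stops earlier at a
fixed point — on clean data the procedure typically converges by iteration
2. Stop codons are never counted in the table.

## Expression and differential calling

FPKM = count × 10⁹ / (length × total_mapped). Total mapped fragments is a
property of the library; `quantify` defaults to the column totals of the
supplied table but accepts explicit library sizes, which matters when the
table covers a subset of the library or when, as in simulations, the true
depth is known (column-total normalization under asymmetric fold changes
introduces a composition bias of several tenths of a log₂ unit).

log₂FC = log₂((FPKM_treated + pseudo) / (FPKM_control + pseudo)) with
pseudo = 0.01 FPKM, keeping fold changes finite when one condition is zero;
the value is configurable. DE is called purely by effect size — up when
log₂FC ≥ 1, down when ≤ −1 (boundaries inclusive) — because a
single-library-per-condition design offers no replication for a variance
estimate; a `min_count` guard (≥ 1 fragment in at least one condition)
suppresses calls made entirely from noise. Isoforms group to genes by the
`comp<digits>_c<digits>` prefix; ids not matching the pattern become
singleton genes. A gene is DE when any isoform is (a gene with both up and
down isoforms is reported as `mixed` and counts as DE). The 2^−ΔΔCT helper
implements relative qPCR quantification against a reference gene.

## Assembly statistics

N50 is the smallest length among the descending-sorted transcripts whose
cumulative sum first reaches half the total. Aggregate GC% excludes
ambiguous bases from numerator and denominator. Histogram bins are
half-open [e_i, e_{i+1}) with a final overflow bin. Annotation percentages
are 100·count/total rounded half-away-from-zero, whole percents by default
and one decimal for rare categories (a 0.4% category would otherwise
vanish); mean length and GC% are reported to two decimals.

## Synthetic data: what it emulates and what it does not

The generator produces data with the structure the pipeline consumes and a
complete truth table (contaminant status, ORF coordinates and strand, true
log₂ fold change, the generating codon table, the seed).

* **Coding transcripts**: 5′UTR + ATG + body codons i.i.d. from a skewed
  codon-usage table + a uniform stop + 3′UTR. The default table weights
  codons by third base (C:6, G:3, A:1, T:1), total-variation distance
  ≈ 0.32 from uniform — a caricature of GC3 bias strong enough to be
  identifiable but not degenerate. UTRs are i.i.d. from a slightly AT-rich
  model (A=T=0.30, C=G=0.20); lengths default to ORFs of 300–900 nt and
  UTRs of 20–200 nt. 20% of transcripts are reverse-complemented so the
  ORF lies on the minus strand, exercising six-frame search.
* **Contaminants**: order-1 Markov sequences. The host-like preset chain
  has mild CpG depletion around a balanced composition; the contaminant
  preset is GC-rich with strong CpG and TpA avoidance. The two presets sit
  ≈ 320 per-mille apart in pooled signature, comfortably beyond the
  150 per-mille separation at which the screen is exercised.
* **Counts**: negative binomial with mean m = base_mean · (length/1000) ·
  (lib_size/10⁶) and variance m + dispersion·m², dispersion default 0.05
  (typical technical-plus-modest-biological overdispersion for bulk
  RNA-seq), base_mean default 50. Treated means are multiplied by
  2^true_log₂FC; planted fold changes default to ±2 or ±3 log₂ units on
  10–15% of non-contaminant transcripts.

Real data differ in ways the generator does not model: codon usage varies
across genes rather than being one fixed table; UTRs and non-coding RNAs
have their own composition; contamination is rarely a single homogeneous
chain; counts carry positional and GC bias and the two libraries share no
true "depth" parameter. Passing tests therefore demonstrate correctness of
the algorithms under their stated model, calibration of the estimators at
adequate depth (fold-change recovery is checked where expected counts are
≥ 50 in both conditions, avoiding selection on noisy observed counts), and
exact agreement with brute-force oracles — not performance guarantees on
any particular real assembly.

## Problem sizes and numerical choices

The seeded simulations use 900 + 100 sequences of 1 kb for the screen, 500
coding + 200 decoy transcripts for ORF self-training, and 800 transcripts
for expression recovery — sizes at which every check completes in seconds
while leaving the measured margins (screen recall 1.0 at FPR ≤ 0.002,
frame accuracy 1.0, table TV ≈ 0.014, |bias| ≤ 0.06) far from their
thresholds. Frequency-vector inputs are validated to sum to 1 within
10⁻⁹. Degenerate inputs fail loudly: all-N sequences are "uninformative",
fewer than two screenable records is "insufficient data", an empty
training set with zero pseudocount is "untrainable", and a pipeline stage
failure aborts the run with the stage name while the manifest marks the
run incomplete. A single global seed expands into per-stage seeds via
`numpy.random.SeedSequence`; identical seeds give byte-identical outputs.

## Known limitations

Single-isoform gene models in the generator (every synthetic transcript is
`_seq1`); no hexamer/Markov coding model (codon preference only); no
splice awareness; DE calling has no error control beyond the fold-change
threshold and min-count guard; the screen cannot separate contaminants
whose composition matches the host.
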
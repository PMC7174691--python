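# Methods

This note documents the models, rules and design choices behind the
package, in the order the pipeline runs them.

## Transcript classification and lncRNA identification

Candidates are assembled transfrags represented as stranded exon chains
(0-based half-open coordinates internally; GTF I/O converts to the 1-based
inclusive convention). Against a reference annotation each candidate
receives exactly one class code, tested in the fixed precedence order
`= > j > o > i > x > u`:

- `=` — exact structural match with a same-strand reference: identical
  intron chain for multi-exon transcripts (terminal exon ends are free to
  differ); for single-exon transcripts, where the intron chain is empty
  and would otherwise match any reference, we require exact exon
  coordinates against a single-exon reference.
- `j` — at least one intron (donor and acceptor both equal) shared with a
  same-strand reference. Single-exon candidates carry no junctions and can
  never be `j`.
- `o` — same-strand exonic overlap without a shared junction.
- `i` — the candidate's whole span falls within a single intron of one
  reference transcript (either strand).
- `x` — exonic overlap only with an opposite-strand reference.
- `u` — none of the above: unknown/intergenic. Candidates on chromosomes
  absent from the annotation are `u` with a logged warning.

Because each code is tested against the entire annotation before falling
through, annotation order never affects the result; this is exercised by a
brute-force checker that applies the definitions with position sets over
every (candidate, reference) pair.

The identification cascade then filters, in order: known-mRNA structures
(code `=`), length < 200 nt, read support < 3, and coding potential. The
coding-potential surrogate is a deterministic ORF rule: a transcript is
coding iff its longest forward-frame ATG-to-in-frame-stop ORF (length
including the stop codon; reading frames on the given strand only) is
≥ 300 nt or covers ≥ 50% of the transcript. This replaces external
SVM/alignment classifiers with something transparent and exactly testable;
300 nt (100 codons) is the conventional boundary below which spurious ORFs
are common in non-coding transcripts, and the 50% coverage arm catches
short transcripts that are essentially one reading frame. An open reading
without a stop codon does not count as an ORF. Each cascade stage emits a
report with retained/rejected counts and per-transcript reasons;
tightening any threshold can only shrink the retained set.

## Expression and differential calls

FPKM is computed from raw counts with the per-sample total counted
fragments as library size: `fpkm[t,s] = counts[t,s]·10⁹ /
(total[s]·length[t])`. No effective-length or TMM-style adjustment is
applied, which gives the exact conservation identity
`Σ_t fpkm[t,s]·length[t] = 10⁹` used as a machine-precision self-check.

For a contrast B vs A (at least two replicates per group):

- `log2fc = log2((mean FPKM_B + 1) / (mean FPKM_A + 1))` — the
  pseudocount of 1 FPKM stabilises fold-changes at low expression;
- p-value from a two-sided Welch t-test on `log2(FPKM + 1)` across
  replicates (a deliberate, documented substitution for assembler-coupled
  DE frameworks, which are out of scope here);
- call = up iff `log2fc > 1` and `p < 0.05`, down iff `log2fc < -1` and
  `p < 0.05`, else ns — strict inequalities, raw p-values. A
  Benjamini–Hochberg FDR column is emitted for information but does not
  drive the calls.

Degenerate rows are resolved explicitly: zero variance in both groups
gives p = 1 when the means are equal and p = 0 otherwise, so no NaN or
division-by-zero propagates. Swapping the groups negates log2fc and leaves
p unchanged.

With n = 3 replicates the Welch test is mildly conservative on
log-transformed negative-binomial counts: the empirical type-I error at
p < 0.05 sits near 0.035 rather than 0.05. This is a property of small-n
Welch testing, not a defect, and stays within the 0.05 ± 0.02 calibration
band the test suite enforces.

## The duplex rule engine

Both site modes classify antiparallel RNA base pairs as Watson–Crick,
G:U wobble, or mismatch, on miRNA positions numbered 1..m from the 5′ end.
Sequences cross the I/O boundary as DNA (ACGT on disk) and are converted
to ACGU internally.

**Cleavage mode** (miRNA-directed slicing of an mRNA) scores an ungapped
window of miRNA length: penalty = Σ w(state)·region with w(mismatch) = 1,
w(G:U) = 0.5, w(WC) = 0, and region multiplier 2 for miRNA positions 2–13
(the seed-through-cleavage core, where pairing matters most); a window is
accepted iff penalty ≤ 4.0. The cutoff and weights are exposed as
parameters; the scheme is a defined, self-contained complementarity
score in the style of plant target-prediction tools.

**Mimic mode** implements the strict plant eTM geometry. For a target
start s and bulge length b, the lncRNA site pairs miRNA positions m..11,
presents b unpaired lncRNA nucleotides strictly between the bases pairing
positions 11 and 10, then pairs positions 10..1. A site is accepted iff

1. positions 10 and 11 are both WC-paired and b ∈ [3, 5];
2. the weighted mismatch total over non-central positions (G:U = 0.5,
   mismatch = 1) is ≤ 4, and no run of more than 2 consecutive
   mismatches occurs — a G:U pair neither increments nor resets a run,
   and the central positions delimit the runs;
3. no gaps or protrusions occur outside the central bulge — enforced
   structurally by the ungapped-arm alignment model.

The middle region is fixed at positions 10–11 (the canonical IPS1-style
eTM geometry). G:U handling is parameterised
(`gu_counts_as_mismatch`, weight 0.5) because conventions differ; the
4-mismatch budget is applied across both arms jointly. The search is
exhaustive over all starts and bulge lengths — transcript scale makes
this affordable — and all accepted sites are reported, including
overlapping ones; there is no per-transcript best-site reduction. An
independent literal enumerator (explicit pair lists, no shortcuts) is held
equal to the engine on tens of thousands of randomized cases.

A consequence of purely local site rules worth knowing: a sequence
containing a near-site (for example a perfect site whose bulge is 2 or
6 nt, or one carrying an inserted nucleotide in an arm) may still contain
a *different*, shifted register in which the bulge window absorbs the
defect and the remaining mismatches fit the budget. Such registers are
genuine rule-satisfying sites and are reported; recovery guarantees are
therefore stated per planted geometry (a planted compliant site is always
reported at its exact start and bulge; a planted violation is never
reported at its planted geometry, and evaluating that geometry yields the
correct failing rule).

## Network assembly

Accepted mimic sites give lncRNA–miRNA edges, accepted cleavage sites
give miRNA–mRNA edges, and every pair sharing a miRNA yields a
(lncRNA, miRNA, mRNA) competition triple. Competition (lncRNA–mRNA)
edges are derived from triples and never stored independently, which
makes the "every competition edge is witnessed by a triple" invariant
structural. The published workflows gate such networks on a loosely
specified "colocalization and expression analysis"; here that is an
explicit, flag-controlled filter (`require_lncrna_de`, default off;
`require_mrna_de` likewise) requiring the lncRNA (or mRNA) to carry a
non-ns DE call, with calls annotated on all nodes either way. Exports:
triple TSV and GraphML with a `nodetype` attribute.

## Synthetic data

The generator emulates the study conditions end to end on a small
two-chromosome genome. Reference mRNAs occupy well-separated 4 kb slots
as three-exon models (300 + 400 + 300 nt); each engineered candidate is
anchored to its own reference gene so class codes are unambiguous by
construction: `i` inside the second intron, `j` sharing the first intron,
`o` overlapping the first exon, `x` opposite-strand over the third exon,
`u` in the downstream pad, plus exact-copy `=` decoys. All non-decoy
candidates are rejection-sampled to be non-coding under the ORF surrogate
so that, with default thresholds, the identification cascade recovers
exactly the planted cohort.

Mimic sites are planted by overwriting the reverse complement of the
miRNA, with the bulge inserted between the bases pairing positions 10 and
11; planted mismatches substitute a base that neither WC- nor
wobble-pairs the miRNA base, so mismatch counts are unambiguous.
Rule-violating sites are planted one per violation class (bulge 2,
bulge 6, five mismatches, three consecutive mismatches, a non-central
protrusion). Cleavage sites (perfect, penalty 0; one-core-mismatch,
penalty 2; and one deliberately failing site, penalty 10) are written
into reference mRNA exons away from any candidate.

Counts follow a negative binomial with mean
`baseline_FPKM · 2^(log2fc·[salt]) · length_kb · depth/10⁶` and variance
`μ + φμ²`. Defaults: 2 genotypes × 2 conditions × 3 replicates
(12 samples), baseline 50 FPKM with a 0.5-log₂ lognormal spread across
transcripts, nominal depth 2·10⁶ fragments with 5% lognormal per-sample
variation, planted |log₂FC| = 2, and dispersion φ = 0.03 — a
well-replicated-experiment value chosen so that the 3-replicate log₂FC
estimator lands within ±0.5 of a planted effect in ≥ 95% of runs, the
calibration the recovery tests assert. The paper-shaped noise model is a
stand-in: no real library-size, GC, positional or isoform-mixture effects
are simulated, so passing tests demonstrate correctness of the inference
chain under NB noise, not robustness to every artefact of real RNA-seq.
`mean_expression` is the baseline against the nominal depth; realized
FPKM depends on how much of the simulated transcriptome the library
covers. Everything is driven by one `numpy` generator seeded from the
config, so a fixed seed gives byte-identical outputs.

## Pipeline

The CLI stages (`simulate`, `identify`, `de`, `targets`, `mimics`,
`network`, `run-all`) are thin wrappers over the library. Configuration
is YAML with unknown keys rejected; every published threshold is a key
with its published value as default. The run manifest records the config
hash, per-output SHA-256 checksums and row counts; a failed stage moves
its partial outputs to `quarantine/` rather than leaving them in place.
`--threads` is accepted for interface stability but execution is
single-threaded (problem sizes here do not warrant more).

## Problem sizes used in the checks

The oracle sweeps use 10,000 random eTM cases (miRNA 15–17 nt, lncRNA
40–80 nt) and 200 random candidates × 20 references; DE calibration uses
10,000 null transcripts across both genotype contrasts and 400 planted
transcripts among 2,000; the end-to-end determinism check runs the full
default synthetic pipeline twice. These sizes make every property
estimate stable to well inside its asserted band while keeping the whole
suite interactive.

## Known limitations

- The coding-potential surrogate ignores homology and codon-usage
  evidence; borderline transcripts that external classifiers would catch
  can slip through (and vice versa).
- FPKM with raw totals is not robust to strong composition effects;
  planting a fold-change on a large fraction of the transcriptome
  visibly shifts the FPKM baseline of everything else.
- The duplex engine is purely combinatorial: no thermodynamic (ΔG)
  folding, no degradome support, no siRNA-generation prediction.
- Single-end evidence such as read_support is taken at face value from
  the annotation; no realignment is performed.
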
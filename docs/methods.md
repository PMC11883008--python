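# Methods

This note documents the models, estimators and numerical choices behind
`sedapop`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the design was genuinely open.

## The simulator (`simdata`)

The generator emulates a well-preserved cold-climate *seda*DNA sample:

- **Fragment lengths** are integer-rounded truncated lognormal draws.
  Defaults `frag_mean_log = 4.2`, `frag_sd_log = 0.35` (median ≈ 67 bp)
  truncated to [30, 150] bp give the short, right-skewed distribution
  typical of sediment extracts; truncation is by rejection, so the empirical
  moments converge to the moments of the truncated distribution
  (`truncated_lognormal_moments` computes them exactly for tests).
- **Deamination** follows an exponential terminal law: at 5′ position *i*
  (1-based) a C is read as T with probability `d_max·exp(−decay·(i−1))`, and
  symmetrically G→A at the 3′ end. The symmetric (double-stranded library)
  signature was chosen because the downstream masking rule treats both
  transition types; a single-stranded mode would mask only C→T. Defaults
  `d_max = 0.02`, `decay = 0.3` sit in the low-single-percent terminal-rate
  regime of Holocene polar deposits. Damage is applied to the fragment in
  its as-ligated orientation *before* sequencing error, so an error can
  revert a damaged base; truth records both event lists separately.
- **Sequencing error** is uniform per-base substitution (default 1e-3) to
  one of the three other bases, applied independently per emitted mate.
- **Sequencing cap**: reads are the first `read_len` bases of the fragment
  (both mates for paired data). For fragments longer than the cap the read
  3′ end is interior to the fragment, so observed 3′ G→A rates are diluted
  relative to 5′ C→T — as in real capped single-end data. Experiments that
  need the full symmetric law set `read_len = frag_max`.
- **Quality strings** are constant Phred 37; QC tests inject low-quality
  bases explicitly.
- All randomness flows from one `numpy` generator seeded per call; identical
  configurations give byte-identical FASTQ and truth output.

Not emulated: indels, PCR duplicates beyond exact re-emission, GC or
fragmentation sequence bias, chimeras, and metagenomic complexity beyond
what the requested reference mixture provides. Passing tests therefore
validate estimator correctness under the stated noise model, not robustness
to every artefact of real libraries.

`generate_references` derives every non-first taxon from the first by
independent per-site substitution, so requested divergence equals expected
pairwise difference; `generate_lineage_haplotypes` builds two clade
ancestors separated by `between_div` and haplotypes mutated at `within_div`,
labelled A/RS in exactly balanced classes.

## Read QC and mapping (`readmap`)

QC keeps reads with length ≥ 30, ≤ 3 N bases, and at most 40% of bases
below Q20 (the unqualified-fraction default of common QC tools; only the
three printed thresholds are pinned).

The mapper is deliberately **exhaustive-verifiable**: exact k-mer seeds
(default k = 13) on both read orientations, every candidate diagonal
extended ungapped across the full read, hits kept with ≤ 10 mismatches and
≥ 95% identity (N counts as mismatch; the identity floor is applied with an
integer-safe budget `min(10, ⌊L·0.05 + 1e-9⌋)` to avoid float-boundary
bugs). Under the 95% identity window a surviving hit always retains at
least one intact 13-mer (at most ⌊0.05·L⌋ mismatches can destroy at most
13·⌊0.05·L⌋ < L−12 seed windows for all L ≥ 30), so the seeded search
provably equals the brute-force all-offset, both-strand scan — which the
tests assert on random instances. Gapped alignment is a non-goal: aDNA
fragments are short and the thresholds cap divergence well below where
indel handling would matter.

The **mapping-quality proxy** is a margin rule, not BWA's formula: unique
hit → 60, best-by-≥2-mismatches → 37, best-by-1 → 25, ties → 0. Downstream
thresholds (≥ 25 for damage profiling, ≥ 20 for diversity) are applied to
this proxy and stated as such. Duplicate removal keeps, per placement
(ref, start, end, strand, mate), the read with the highest summed base
quality (stable tie-break by read id); pair filtering requires both mates
on the same reference within a 1000 bp insert (the insert bound is this
package's addition; same-reference pairing is the pinned rule).

## Damage profiling (`damage`)

Substitution counts are tabulated in read orientation for positions 1..25
from each end (reverse-strand hits use the reverse-complemented reference
slice), pooled across references — the merge-reference-sequences behaviour
is the only mode. Rates with zero denominator are NaN. Only substitution
tables are implemented; Bayesian fragmentation-model fitting and quality
rescaling are out of scope. With sequencing error *e* and no damage the
expected position-1 C→T rate is *e*/3, which the validation experiments
check to 3 binomial standard deviations.

## LCA profiling and decontamination (`taxprofile`)

"Similarity" is interpreted as identity over the full read; for ungapped
hits the edit-distance window of LCA classifiers collapses to the mismatch
count, so the 0–10-mismatch and 95–100% windows are applied directly. The
LCA of the surviving hit taxa is the longest shared root-path prefix
(unique by construction; validated against brute-force ancestor-set
intersection on random trees).

Decontamination runs as sequential stages: per-cell minimum of 3 reads; a
minimum read percentage knob (default 0, a deliberate no-op kept for
parity); minimum 50-read taxon sum including controls; removal of taxa
detected in any control in *all* samples (removal, not per-sample
subtraction) unless allowlisted by node id or name; removal of *Homo
sapiens*, Primates and their descendants; then controls are dropped and a
final 20-read sum over the remaining samples is applied. The final
threshold is applied after dropping controls because it defines the "final
profile" of the real samples. The result is monotone (no cell increases,
taxa only removed). With no flagged controls the control stage is skipped
with a warning.

Pseudo total-sum scaling divides each cell by its sample's row total of the
current matrix; all-zero samples stay zero. Group rollups assign each node
to its nearest (deepest) listed group ancestor so that groups plus "other"
partition the total; overlapping units (a kingdom and one of its phyla) can
be reproduced by rolling up against one level at a time.

**A boundary worth knowing:** when two taxa diverge at exactly the identity
window (5%), cross-taxon hits pass the filter about half the time and the
LCA conservatively pushes those reads to the root. That is correct,
deliberately cautious behaviour — but it means species-level proportions
are only recoverable for taxa diverged beyond the window, which is how the
mixture-recovery test is constructed (10% divergence).

## Lineage voting (`lineage`)

The haplotype database is deduplicated by exact sequence and the larger
class down-sampled (seeded, order-preserving) to the smaller class's size,
yielding exactly balanced A/RS panels. Votes are counted **one per distinct
reference** (best hit per reference by identity, then mismatches), because
the minimum-unique-reference filter is phrased in references and raw hit
counts would double-count multi-placements. An e-value cut-off is not
meaningful for the seeded ungapped mapper and is non-binding at ≥ 95%
identity on ≥ 30 bp reads; the seed requirement plus the identity filter
replace it. Pairs with < 3 distinct surviving references are unassigned;
the > 70% majority is strict (7 of 10 is undetermined). Per-sample
proportions exclude undetermined and unassigned pairs from the denominator
but report them; with two clades ~5% apart and short reads a large
undetermined fraction is expected and harmless, because by label symmetry
the exclusion does not bias the A:RS ratio — the validation experiment
recovers mixture truths {0, 0.1, 0.3, 0.5} within ±0.01 at 10k pairs.
Reads, not individuals, are the unit; no haplotype reconstruction is
attempted.

## Nucleotide diversity (`diversity`)

π is computed directly from pooled read-level allele counts rather than
via genotype calls: the masking and depth filters act on read calls, and
pooled-sample semantics is the natural reading for multi-individual
sediment samples. Masking recodes only *mismatching* C→T / G→A read bases
within 10 nt of either read end (in read orientation; reverse-strand hits
on their reverse-complemented view) to N with quality 0. The pileup counts
non-N calls from hits with mapping quality ≥ 20; sites with depth < 2 have
no data. Per-site π uses the n/(n−1) small-sample correction and equals
the unordered-pair mismatch fraction exactly.

"Sites with data" means **all** reference sites with post-masking depth
≥ 2, not variant sites only: the adjusted-sample-size language implies a
coverage denominator. Both means (all covered sites, variant sites only)
are computed and reported so the interpretation can be compared. No indels
exist in the ungapped mapper, so indel exclusion holds by construction.
Masking biases π downward at genuine C/T or G/A polymorphisms near read
ends; the validation experiments use complement-transversion variants so
the analytic truth is exact, and real C↔T variation should be interpreted
with this in mind.

`max_upper_pi` takes, per colony, the maximum per-sample mean π among
samples within the uppermost 10 cm of the stratigraphy (the most recent
past); colonies with no sample that shallow are flagged missing.

## Group statistics (`report`)

Welch's t with Welch–Satterthwaite degrees of freedom and two-sided
p-values from the t distribution; both-variance-zero inputs with equal
means return t = 0 with the df flagged degenerate. OLS via
`scipy.stats.linregress` with r² = 1 − SSres/SStot. No multiple-testing
correction is applied. The stratigraphic table is pure formatting: samples
ordered by depth within site, with π, lineage proportions, damage rate and
a fish:krill read-count ratio (zero denominators flagged) as columns.

## Validation experiments (`experiments`) and problem sizes

The experiments module re-runs each estimator against an oracle or known
truth at sizes chosen to make stochastic checks sharp yet fast on one CPU:
50k reads for damage-rate recovery (±0.005 at d_max = 0.04), 10k read
pairs per mixture for lineage recovery (±0.03 bands), depth 50 over 1 kb
for π recovery (within 15% of the analytic truth), and an analytic residual
floor for the masking experiment: with E expected spurious surviving calls
among N retained calls, each creating a depth-n singleton worth 2/n at its
site, the expected mean π is 2E/N with Poisson standard deviation
2√E/N. E sums, over reads, interior deamination survival
(f_CG · d_max · Σ e^(−decay·i) over unmasked positions) and sequencing
errors (in-window errors count unless they mimic damage, a 1/3 fraction at
C/G sites).

## Known limitations

- The mapq proxy is coarser than an aligner's posterior; thresholds on it
  are reproducible but not numerically comparable to BWA values.
- Reads with every k-mer destroyed cannot seed; this is impossible within
  the 95% identity window (see above) but matters if the window is relaxed.
- The decontamination removes taxa globally on control detection; low-level
  cross-contamination of genuinely present taxa is removed with it unless
  allowlisted.
- Terminal masking trades variance for bias at genuine terminal C/T, G/A
  polymorphisms (see above).
- Group-level damage summaries, fragment-length contrasts between real
  colony-age classes, and the published colony-size regression depend on
  field samples; the package reproduces the estimators and the machinery,
  and validates them on synthetic truth only.
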
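# Methods

This note documents the models, conventions, numerical choices, and known
limitations of the `agosort` pipeline.

## Coordinates, alphabets, anchoring

All sequences are RNA (A/C/G/U, uppercase); DNA input is transliterated on
load. Positions are 1-based from the 5′ end. Positional analyses anchor
sequences on the 5′ terminus because the miRNA 5′ end is held in the AGO
MID-domain binding pocket — the structurally homologous position across
miRNAs is therefore the distance from the 5′ end. Mutual-information and
logo analyses use 5′-anchored 21-mers; forest features use 24 positions
with 3′ N-padding (sequence mode) or unbound-padding (pairing mode), so
sequence length is implicitly encoded in the trailing pad states.

## Confidence set

Reads are trimmed by exact-substring adapter search and capped at 30 nt;
counting matches each mature miRNA against each read as an exact
substring. A read containing several distinct mature sequences increments
each of them — miRNAs are quantified independently, with no unique
per-read assignment, which is equivalent to end-to-end exact mapping of
each miRNA against the read set. RPM uses the per-library totals; when no
explicit totals are given they default to column sums and the table is
flagged `derived` (real co-IP totals include reads matching no miRNA, so
both modes are supported). A miRNA is labeled with an AGO when one
library's share of its summed RPM is strictly greater than 0.70 and its
summed RPM is at least 10 (exclusion is strictly `< 10`); shares can
optionally be computed on raw counts instead (the two differ when library
depths differ; RPM shares are the default). At most one library can exceed
a 0.70 share, so labels are mutually exclusive by construction. Identical
mature sequences collapse to one entry (conflicting labels for the same
sequence are an error, since counting operates on the sequence);
sequences shorter than 21 nt are kept only for the padded forest analyses.

## Duplex inference

The mature and star strands (star taken from the record or sliced from
precursor coordinates) are stripped of their 2-nt 3′ overhangs and
globally aligned (star reversed, antiparallel) under a fixed pairing
score: Watson–Crick +2, G:U wobble +1, other aligned pair −1, gap −2.
Score ties prefer fewer gaps, then earlier aligned columns (leftmost gap
placement), making the alignment deterministic. Mature positions are
classified WC / wobble / unpaired; gapped mature positions count as
unpaired. `n_mismatches` counts aligned non-pairing columns once per
mature position; `max_bulge` is the longest gap run on either strand.
This replaces minimum-free-energy hybridization: for the near-complementary
duplexes that pass the precursor filter the two agree on the pairing
pattern, and externally computed structures can be imported as state
strings (`W`/`w`/`U` per position) to swap the aligner out entirely.
Precursors fail the quality filter iff mismatches > 6 or a bulge > 3 nt
(both strict). Pairing-frequency profiles stop at position 19 because the
2-nt overhang of a 21-mer leaves pairing undefined beyond it.

## Mutual information and significance

MI is computed from empirical joint frequencies in bits; zero-probability
cells contribute nothing. The null distribution shuffles the label vector
independently per position (base composition of each column is preserved).
Empirical p-values use the add-one convention p = (1 + #{MI_null ≥
MI_obs}) / (n_perm + 1), so p is never zero and a constant column (all
shuffles tie at MI = 0) gets p = 1. The library default is 10,000
shuffles; tests and the acceptance script use 999 (the +1 convention makes
the resulting p-grid 1/1000-spaced, sufficient for 0.05-level decisions).
BH-FDR is applied across the 21 positions of a profile. Star-strand
profiles support two anchorings — the star's own 5′ end, or columns
indexed by the mature position each star base sits opposite in the duplex
— because the structurally relevant register for the passenger strand is
ambiguous.

## Composition and logos

Enrichment ratios are relative frequencies: (class base frequency) /
(background base frequency), with 0 for empty classes and an infinite
flag when a base absent from the background appears in a class. Logo
information content is R_i = 2 − H_i bits; the small-sample correction
e_n = 3/(2 n ln 2) is available but off by default (heights are then
frequency × R_i, floored at zero).

## Random forest

The forest is written from scratch because its required semantics —
categorical splits by exhaustive binary subset enumeration (feasible with
alphabets of at most five symbols), a balanced bootstrap of exactly
`sampsize` draws with replacement per class, OOB vote bookkeeping per
tree, and unscaled permutation importance — are those of the classical R
implementation and are not reproducible with one-hot encodings (which
change the meaning of `mtry`). Defaults: 500 trees, sampsize 20, mtry =
⌊√p⌋, trees grown to purity, vote ties broken by the fixed sorted class
order (AGO1 < AGO2 < AGO5). OOB accuracy is computed over samples with at
least one OOB tree; samples never out of bag (vanishingly rare at 500
trees) are excluded and logged. The implementation was cross-checked
against R `randomForest` with stratified `sampsize = c(20,20,20)`: both
give the same OOB accuracy on separable data and the same class-shuffled
behaviour (see below).

**A structural property worth knowing:** with a *balanced* per-class
bootstrap on an *unbalanced* cohort (70/25/22), class-shuffled OOB
accuracy does not sit at 1/3 but near 0.44 — large classes are
over-represented both among OOB-scored samples (their members are drawn
less often) and among distinct in-bag exemplars. R `randomForest` behaves
identically (0.446 ± 0.042 vs 0.443 ± 0.045 here, noise features). The
chance-level baseline of 33% for three classes therefore refers to the
balanced setting, and the calibration checks in this package use three
balanced classes of 39.

The comparison protocol trains both feature conditions with the same
per-run bootstrap seed (so identical conditions yield identical margins
and p = 1), computes per-sample OOB margins, applies the two-sided
Wilcoxon rank-sum test (exact for ≤ 25 per group without ties, otherwise
the tie-corrected normal approximation), and reports the median p over
runs — a bootstrap-style estimate that respects the original dataset size
rather than accumulating evidence across repetitions. Class-shuffled
conditions draw a fresh label permutation every run. The library default
is 1,000 runs; the test suite and acceptance script use 100 runs and
100–300 trees to keep repeated-run protocols fast — at these sizes the
median p and mean accuracies are stable to well within the decision
thresholds used.

## Synthetic data

The generator emulates the statistical structure of AGO co-IP
experiments, with defaults set to the study conditions this package is
designed around:

- **Cohort**: class sizes 70 (AGO1), 25 (AGO2), 9 (AGO4), 22 (AGO5);
  class-conditional 5′-base distributions matching the observed
  composition (AGO1 0/6/1/63 over A/C/G/U, AGO2 21/0/1/3, AGO4 5/0/0/4,
  AGO5 0/6/0/16); all other positions i.i.d. uniform. Sequence length 21.
- **Nested rules** plant conditional two-position signals (both outcome
  classes share the condition base; the decision position's base set
  determines the class), which are invisible to univariate statistics by
  construction.
- **Libraries**: per-AGO depths default to the four co-IP library totals
  scaled by 1/100 (32,413 / 7,718 / 21,485 / 8,747 reads) to keep
  read-level simulation tractable; per-miRNA abundance is log-normal
  (σ = 1); the preference of a miRNA for its true AGO is Dirichlet with
  concentration 20 on the own class and 1 elsewhere (the 70% rule then
  labels most but not all miRNAs, matching the ambiguity observed in real
  co-IP data); 10% of reads are random unassignable sequences. Reads are
  the mature sequence plus a fixed 3′ adapter, truncated to 30 nt.
- **Hairpins**: precursor = mature + loop + star arm with canonical 2-nt
  3′ overhangs; wobbles, mismatches, and bulges are planted at requested
  mature positions. Bulge insert bases are chosen to not pair with the
  local mature window so the planted structure is the unique optimal
  alignment.

What the generator does *not* model: sequencing errors, isomiRs,
expression-correlated preferences, realistic (non-uniform) background
base composition away from the signal positions, cross-mapping between
family members, or secondary-structure thermodynamics. Passing tests
therefore demonstrate the correctness and calibration of the *methods*
under controlled signals, not the biological conclusions one would draw
from real libraries — real co-IP data (FASTQ + miRNA annotations) can be
run through the same CLI stages for that purpose.

## Numerical and edge-case conventions

Threshold comparisons follow the stated rules strictly (> 70%, < 10 RPM,
> 6 mismatches, > 3 nt bulge). Empirical p-values are never 0; BH output
is monotone and capped at 1. Degenerate single-library draws clamp a
zero-read library total to 1 so count-table invariants hold. MI columns
must be pure A/C/G/U (the 21-mer trim guarantees this; N never reaches
the MI engine). The correlation helper refuses profiles with zero
variance or fewer than 3 points. All randomness flows through
`numpy.random.Generator` seeded from the run config, and every output
manifest records the seed; identical config + seed reproduce byte-identical
tables.

## Known limitations

- The duplex aligner scores a fixed pairing scheme; strongly defective
  duplexes (many mismatches *and* bulges) can have co-optimal alignments
  whose mismatch/bulge split differs from an MFE tool's — such records are
  typically rejected by the quality filter anyway.
- Symmetric internal loops count one mismatch per mature position
  involved, which may differ from tools that count loops once.
- The expected 52%/64%/42% accuracies reported for real co-IP data are
  not reproducible without those libraries; the package asserts
  property-based behaviour (chance baselines, planted-signal recovery,
  condition orderings) instead.
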
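# Methods

This note documents the models, statistics and design choices behind
`maedeconv`, in the order the pipeline applies them, together with the
assumptions each step makes and the limits of what the synthetic-data
tests can show.

## Identification-level filtering

A peptide observation is a row of a search-engine export: sequence,
optional protein provenance (1-based inclusive coordinates, UniProt
convention), cell line, replicate, spectral count, optional intensity.
Column mappings are dialect-driven (`default`, `maxquant`, `fragpipe`, or
a user mapping), so the pipeline starts after identification and never
parses raw MS formats. Sequences are restricted to the 20 standard amino
acids; B, J, O, U, X, Z are rejected at the boundary with the offending
row named.

The replicate-consistency rule retains a (sequence, cell line) pair iff
the peptide was seen with a positive spectral count in at least
`min_reps` (default 2) of `total_reps` (default 3) replicates. A zero
count is "not observed": identification implies at least one spectrum.
The rule is exposed as a config switch (default on) because some study
designs apply it only to a subset of samples. Peptides of 8 or fewer
residues are rejected before condensation — the MHC I groove prefers
9-mers, and shorter sequences are overwhelmingly non-specific.

## Epitope condensation and classification

Antigen processing and handling produce nested length variants of each
presented ligand; counting variants separately overstates sample
complexity. Overlapping peptides are therefore condensed into the longest
possible sequence (the epitope):

* **coordinates mode** — peptides on the same protein merge when their
  intervals overlap by ≥ 1 residue; each maximal connected component
  yields one epitope spanning the union interval. Peptides mapping to
  multiple accessions are assigned the lexicographically smallest (logged)
  so the grouping is order-free.
* **string mode** — for tables without coordinates. Two peptides overlap
  iff one contains the other or a suffix of one equals a prefix of the
  other with length ≥ `min_overlap` (default 5 — shorter accidental
  overlaps would glue unrelated peptides). Components merge via BFS
  placement from the lexicographically smallest member, taking the
  maximal admissible overlap per edge; inconsistent letters at a shared
  position abort with the component listed.

Both modes are deterministic and permutation-invariant; on data with
known coordinates string mode reproduces coordinate mode whenever true
overlaps meet `min_overlap` (tested).

Classification: epitopes with total spectral count below 3 are rejected
(low technical confidence), 9–11-mers are MHC I, 12–20-mers are MHC II
but must contain ≥ 3 distinct constituent peptides — single long peptides
without a nested set are treated as contaminants. Spans beyond 20
residues are rejected with a warning (config flag to retain them
unclassified); the count filter is applied before class assignment.

## Abundance indices

P_i (Peptide Index) is the mean spectral count over a line's replicates,
*zero-inclusive*: the sum over replicates divided by `total_reps`, so a
peptide seen in 2 of 3 replicates with counts (3, 5) has P_i = 8/3. This
makes P_i comparable across peptides with different detection rates.
E_i (Epitope Index) is the sum of the constituent peptides' P_i; summing
E_i over all epitopes of a class therefore conserves the summed P_i
exactly (a tested identity). Both scale linearly with counts.

The knockdown comparison normalizes intensities by per-sample total
scaling to a common sum (the simplest defensible choice; config-exposed),
assigns sample-exclusive peptides the sentinel ratios 50 (absent from
control) and 0.02 (absent from knockdown), and calls a peptide *affected*
when ratio ≤ knockdown factor (default 0.21, the measured fraction of
target protein remaining; the boundary is inclusive).

## Centroid-linkage clustering

Implemented directly rather than through a Lance–Williams recurrence:
cluster-to-cluster distance is the metric distance between centroids
re-derived as member means at every step, which is what Cluster 3.0
computes and which can produce non-monotone merge heights (accepted).
Default metric is 1 − Pearson correlation (centered); Euclidean is
available, and for Euclidean the heights coincide with
`scipy.cluster.hierarchy.linkage(method="centroid")` (used as an
independent cross-check in the tests). Zero-variance vectors get
distance 0 to an identical vector and 1 to anything else. Ties in the
minimum distance break on the sorted pair of each cluster's oldest
member index, making results independent of input order. No log
transform is applied to E_i by default; the matrix is clustered as
computed.

Nodes are the leaf sets of internal vertices with 9–100 members (both
bounds config-exposed; the same defaults are used for MHC I and MHC II
since no separate class I window is established). Nested qualifying
vertices all yield nodes, so an allele's epitopes typically contribute a
chain of nested nodes.

## Offset-only node alignment

At MHC peptide lengths, alignment under a prohibitive gap-open penalty
degenerates to sliding ungapped sequences; the module implements that
regime explicitly instead of shelling out to an external aligner: one
integer offset per sequence, terminal gaps free, width capped at 12
columns (MHC I) or 30 (MHC II). Placement is progressive — seed = the
highest-E_i epitope (ties: longest, then lexicographic), each remaining
sequence takes the offset maximizing its summed BLOSUM62 score against
the current column profile (ties: smaller width, then smaller offset) —
and placed offsets never change. The progressive pass is exactly optimal
for two sequences and for nested ragged sets (substrings of one span),
and is bounded above by the exhaustive sum-of-pairs optimum always; on
3–4 weakly-related sequences it can commit early to a locally best
placement, which exhaustive search beats on roughly 10–20 % of random
anchor-style nodes (both numbers are measured and reported by the
acceptance script). Revising earlier offsets would repair those cases
but would break the progressive contract, under which adding a sequence
never moves sequences already placed — a property downstream consumers
may rely on and which the tests assert.

## Logo statistics and consensus rendering

Per alignment column with N_n residues out of M sequences:

* weight W = N_n / M;
* information content E = max(0, log2 20 − H − e_N), with H the plugin
  entropy of the residue frequencies and e_N = 19/(2 ln 2 · N_n) the
  standard small-sample correction for a 20-letter alphabet (this is the
  compositional-bias compensation);
* L, the lower 95 % bound on E, from a seeded multinomial bootstrap (200
  resamples of size N_n by default): L = E − (Q97.5(E*) − Q2.5(E*))/2,
  clamped to [0, E]. The interval is *centered on E* rather than read off
  the raw E* percentiles because the plugin entropy of a resample is
  biased low, so E* overshoots E; the raw 2.5th percentile then lands at
  or above the point estimate on low-information columns, collapsing the
  threshold to zero and flagging pure noise as significant (measured:
  22/30 uniform columns falsely significant with the raw percentile, 0/30
  with the centered interval, while 29/30 genuine anchor columns remain
  significant). A literal one-sided 95 % bound was evaluated and is
  empirically indistinguishable from the centered two-sided construction.

Scores: S_x = (A_x/N_n) · E · W for each residue (so Σ_x S_x = E · W
exactly), and R = E − L. A residue is significant iff S_x > R (strict —
the exact comparison is a design choice, flagged here). Residues failing
alone may pass grouped: a physicochemical group ({A,V,L,I,M}, {F,W,Y},
{K,R,H}, {D,E}, {S,T,N,Q}, {C}, {G,P}; config-overridable) is significant
when its summed S exceeds R and no member passes individually. Grouping
deliberately trades residue-level resolution for sensitivity, which
matters for the more degenerate MHC II motifs.

Rendering: positions with nothing significant are dashes; significant
positions are written regular-expression style (`[XY]`), uppercase for
individually significant residues, lowercase for group-only; grayscale
shade = S clamped to [0.2, 1.0] (S is capped only for shading, never for
selection). The `top4` style keeps the four (position, residue) entries
with the highest S across the whole line (per-line, not per-position —
the summary-view reading); `top4_dashed` additionally dashes the
non-significant positions inside the retained span.

## Allele deconvolution and traceability

Theoretical profiles binarize genotypes: profile[c] = 1 iff the allele
appears in line c's typing. Observed epitope rows binarize as E_i > 0
exactly (a positive floor is available for noisy data). Candidates are
all alleles within Hamming distance `max_mismatch` (default 0) of the
binarized row; co-segregating alleles share profiles and remain
ambiguous by design, and an empty candidate set flags a putative
contaminant. Node-level assignment (binarized mean profile) and
epitope-level assignment are both exposed. MHC II heterodimer pairing
(cis/trans DQ/DP combinations) is out of scope; class II alleles are
matched individually, which understates the true ambiguity of class II
deconvolution.

An allele is *traceable* when its presence vector is unique. Across-loci
uniqueness (the stricter default) is identically zero under pure
whole-haplotype inheritance — every allele shares its vector with its
haplotype partners at other loci — so a per-locus mode is provided and
used in the panel reports, answering the practical question "given the
epitope's class and locus candidates, does the profile pin the allele?".
The count is monotone non-decreasing as lines are added (property-tested
and oracle-checked).

## Benchmarking

Binder predictions are ingested, never computed: a parser maps a
%Rank-bearing table to strong/weak/none calls (defaults 0.5/2.0 for
class I, 1/5 conventionally for class II — parser thresholds, not
predictions). A sequence is a binder iff strong or weak for ≥ 1 queried
allele; precision = TP/(TP+FP) over the retained set, undefined (NaN,
with a warning) when nothing is retained. Random negative-control
peptides are uniform over residues and lengths, seeded.

## Synthetic family peptidome

The generator emulates the study design the pipeline targets, with every
default chosen as the realistic condition, fixed once:

* **Panel**: 2 parents + 5 children (7 lines). Parents carry four
  distinct haplotypes per panel (4 distinct alleles per locus from a pool
  of 6); children inherit one complete haplotype from each parent, no
  recombination — HLA is tightly linked. With 5 children over 4 possible
  haplotype combinations, at least two children share a genotype, which
  the cell-line dendrogram must recover.
* **Loci**: A, B, C (class I), DRB1, DQB1 (class II).
* **Motifs**: per allele, anchor residues drawn at positions 2 and 9
  (MHC I) or core positions 1, 4, 6, 9 (MHC II), present with probability
  0.8, other positions uniform. Anchors sit at absolute positions 2 and 9
  for all class I lengths 9–11; the C-terminal-anchor biology of
  10/11-mers is deliberately not modeled.
* **Epitopes**: 20 per allele — enough that single-allele nodes reach
  the ≥ 20-sequence regime where logo significance is well-powered.
  MHC I epitopes emit the full-length peptide and, with probability 0.5,
  one nested sub-peptide; MHC II epitopes emit 3–6 nested ragged 12–20
  mers (flanks of 2–5 residues around the 9-mer core; configurations
  whose core plus flanks could exceed 20 are rejected). Each epitope
  lives in its own synthetic protein at known coordinates.
* **Counts**: Poisson per replicate with mean
  `count_lambda · f_epitope · f_presentation`, where `count_lambda` = 12
  (a typical average spectral count for confidently identified MAE
  ligands), f_epitope is a clipped lognormal immunodominance factor
  (σ = 0.3, range [0.7, 1.6]) and f_presentation a per-(allele, line)
  presentation-efficiency factor (σ = 0.6, range [0.5, 3.0]). The line
  factor is what makes abundance clustering able to separate
  co-segregating alleles — with flat abundances their E_i patterns would
  be mathematically indistinguishable (identical supports), contrary to
  how real allele-specific expression behaves; the lower clip keeps the
  minimum effective Poisson mean near 5 so that, at zero dropout,
  detection of a carried epitope in a line is essentially certain and
  the zero-noise recovery guarantees are properties of the model rather
  than luck.
* **Noise**: replicate dropout 0.1 and contaminant fraction 0.1 by
  default (the zero-noise tests set both to 0). Contaminants are uniform
  random sequences of length 8–20, present in every line — the length
  filter, the class II nesting rule and profile matching each remove a
  share of them, which is the mechanism the pipeline relies on for real
  data.

Everything derives from a single seed (family and peptidome on separate
derived streams); identical configs give byte-identical output files.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: a realistic proteome background and shared
source proteins (epitopes never collide on one protein), intensity-based
quantification, chimeric/cis-spliced peptides, allele-specific length
preferences beyond the planted weights, MHC II binding-core placement
variability within the nested set, and linkage patterns other than
perfect haplotype transmission.

## Numerical and determinism notes

All stochastic components (bootstrap, simulation, random peptides) take
explicit seeds and use independent derived streams; per-column bootstrap
seeds derive from the logo seed and the column index. Clustering and
condensation are deterministic with documented tie-breaks. Merge heights
are floated at ≥ 0 (correlation distance can round to −1e−17). Epitope
ids are assigned after a canonical sort (protein, start, sequence), so
input order never leaks into outputs.

## Known limitations

* The progressive aligner is not globally optimal for ≥ 3 weakly-related
  sequences (quantified above); nodes whose members share a genuine motif
  or nesting structure are aligned at or near the optimum.
* Logo significance at node sizes near the minimum (9–12 sequences) has
  limited power for anchors carried by ~60 % of members; the grouped
  significance path recovers part of it.
* Across-loci traceability is uninformative for pure-haplotype panels
  (see above); use the per-locus mode.
* String-mode condensation can, in principle, choose a spurious maximal
  overlap between coincidentally repetitive peptides; with `min_overlap`
  = 5 over the 20-letter alphabet this is vanishingly rare and surfaces
  as an explicit conflict error, never silent corruption.
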
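# Methods

This note documents the models and procedures `tcrtrace` implements, the
defaults and why they were chosen, what the synthetic cohort generator
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## Clone model and normalization

A clone (clonotype) is the triple (V gene, J gene, CDR3 amino-acid
sequence). Gene calls are reduced to gene level by stripping allele
suffixes (`TRBV5-1*01` → `TRBV5-1`) because upstream pipelines and
public databases mix allele- and gene-level conventions; the original
call is retained on the clone for provenance. Rows with an empty CDR3, a
character outside the 20 standard amino-acid letters, or a non-positive
count are dropped at ingestion and the dropped count logged — a
conservative quality filter, since no universal QC rule exists for
clone-table exports. Duplicate keys merge by summing counts. Frequencies
are recomputed from counts on every load (`f_i = c_i / Σc`), never
trusted from a file; this single normalization authority guarantees
`Σ f_i = 1 ± 1e-9` on every path into the library.

The subpopulation vocabulary carries both sorting granularities seen in
two-arm designs — pooled `CD4_memory`/`CD8_memory` compartments in one
arm and `CM`/`EM`/`TEMRA` in the other — and performs no automatic
pooling, mirroring how the samples were sorted. The cohort loader makes
no completeness assumption (a patient may lack subpopulations or a
timepoint); pairing steps skip and log missing partners.

## Diversity and clonal-expansion profiles

Shannon entropy uses the natural logarithm throughout, so that the
exponential in the evenness definition cancels the base:
`S-E = exp(−Σ f_i ln f_i)/SR`. Hill diversity
`qD = (Σ f_i^q)^(1/(1−q))` is evaluated directly except at the q = 1
singularity, where the closed-form limit `exp(H)` is returned (inputs
with |q − 1| < 1e-9 are routed to the limit; no numerical
interpolation). `0D` returns SR exactly. The clonal-expansion profile is
`qD/SR` on the grid q = 0, 0.2, …, 10 (51 points, configurable). Profile
values are in (0, 1], equal 1 at q = 0 by construction, and are
non-increasing in q — a property test checks this on random frequency
vectors.

Floating-point caveat: for a uniform repertoire the evenness identity
`S-E = 1` holds to ~1e-15 but not bitwise, because `f ln f` terms round;
tests therefore assert |S-E − 1| ≤ 1e-12 rather than equality, and no
uniformity special-case is hidden in the implementation.

Profiles are correlated across samples as raw vectors with Pearson r
(log-scaling the profile values first is offered nowhere because it
changes the statistic; users can transform the exported profile table
themselves). Pairs involving a zero-variance profile (e.g. two perfectly
even repertoires, both profiles constantly 1) are undefined and reported
as NaN; the matrix diagonal is fixed at 1 by convention. Hierarchical
clustering of correlation matrices uses correlation-based distance
`d = 1 − r` with average linkage by default — the linkage is a
documented package choice, since distance alone does not pin down a
dendrogram — delegated to `scipy.cluster.hierarchy`. Degree-matrix
heatmaps cluster samples by Euclidean distance on their degree-fraction
vectors, again with average linkage.

## Clonal persistence and publicity

Persistence between repertoires A and B counts shared clone keys (no
frequency weighting — the statistic counts clones):
`100 · |A∩B| / mean(|A|,|B|)` with the arithmetic mean. It is symmetric,
bounded in [0, 100], and undefined (an error) for empty repertoires. The
default pairing rule compares every t0 subpopulation of a patient with
every t24 subpopulation (the per-patient table layout); a `matched` rule
restricts to same-subpopulation pairs.

A clone is public when present in ≥ 2 sharing units and private
otherwise. The default unit is the *sample* (the formal definition);
patient-level pooling is exposed as an option because public clones are
sometimes counted across patient repertoires instead. Highly-shared
clones use a `min_samples` threshold, default 11 (i.e. "more than 10
samples"), always counted at sample level.

## LD-1 networks and k-mer spectra

Network nodes are the top-N CDR3 strings by aggregated clone frequency
(default N = 10,000; clones sharing a CDR3 through different V/J genes
collapse into one node with summed frequency, since the network is
defined on amino-acid sequences). Ties break by higher frequency then
lexicographic CDR3 for determinism. Edges connect distinct strings at
Levenshtein distance exactly 1.

Neighbor search is a wildcard-pattern hash join: equal-length strings at
Hamming distance 1 share a single-position wildcard pattern, and a
string is at distance 1 from one a single character longer iff it equals
one of the longer string's single-character deletions; strings whose
lengths differ by ≥ 2 can never be at distance 1. This is O(total string
length) in hash operations rather than O(n²) in string comparisons, and
is *required* to be edge-identical to brute-force all-pairs Levenshtein
— the acceptance suite checks 20 random fixtures up to 2,000 strings
against an independent implementation (edlib). Node size scaling with
log clone frequency is carried as an export attribute
(`log_frequency`), not a computed statistic. Edges are inserted in
sorted order so GraphML/edge-list exports are byte-stable across
processes.

Connected fractions report the percentage of nodes of a publicity class
(private/public/all) with degree ≥ 1; an empty class yields NaN, and the
all-class fraction is the membership-weighted average of the private and
public fractions.

k-mer profiles cut each CDR3 into its overlapping length-k subsequences
(default k = 3) and normalize the aggregate counts to sum 1. The default
weighting counts each *distinct CDR3* once (sequence-level counting);
clone-frequency weighting is exposed as an option because either reading
of "frequency across all CDR3s" is defensible. CDR3s shorter than k are
skipped with a logged count. Cross-sample comparison aligns profiles on
the union of observed k-mers with zero fill before Pearson correlation.

## Database annotation

McPAS-TCR (CSV) and VDJdb (TSV, TRB rows only) export layouts are
parsed with configurable column maps; literature sets are plain
one-CDR3-per-line lists. CDR3s are uppercased and deduplicated with the
union of their category labels. Matching is exact string equality on the
CDR3 (optionally the full V-CDR3-J key); boundary residues are never
trimmed or added, because C…F conventions differ across databases and
silent editing is worse than a documented exact-match contract. Overlap
percentages are relative to the sample's species richness; the per-
category counts let the database-relative alternative be computed from
the emitted tables. Database files are user-supplied snapshots — counts
depend on the snapshot version, so nothing is fetched from the network.

## Group statistics

Between-arm contrasts (different patients) use the unpaired Wilcoxon
rank-sum test; within-patient t0-vs-t24 contrasts use the paired
signed-rank test, matched by patient. Small samples (combined n ≤ 12)
without ties use the exact null distribution; otherwise the normal
approximation with tie correction, as in R's `wilcox.test`. The exact
two-sided p-value convention is `min(1, 2·min(P(U ≤ u), P(U ≥ u)))`,
verified against full enumeration of label assignments in the test
suite. A paired contrast whose differences are all zero is flagged
degenerate (p = NaN) instead of tested. Raw p-values are primary, with
the conventional thresholds annotated (* p < 0.05, ** p < 0.01);
Benjamini–Hochberg adjusted values are emitted alongside as good
practice.

## Synthetic cohort generator

The generator emulates the *statistical* structure the analyses consume,
not T-cell biology — no V(D)J recombination model, no thymic selection,
no antigen-driven dynamics:

- **Design**: 7 patients with 4 subpopulations (naive/memory CD4 and
  CD8) in the transplantation-style arm and 8 patients with 7
  subpopulations (naive/CM/EM plus CD8 TEMRA) in the antibody-style arm,
  each at t0 and t24 — 168 repertoires at the defaults.
- **Clone frequencies**: geometric rank law `f_i ∝ exp(−a·i)` with
  polarization a ≥ 0 (a = 0 is uniform). Chosen over a power law for
  closed-form control of evenness — the analyses need tunable
  polarization, not a fitted biological law. The effective per-sample
  polarization is the spec value times a fixed compartment factor
  (naive 0.6 < CM 1.2 < memory 1.4 < EM 1.5 < TEMRA 1.8; naive
  repertoires are more even than memory in sorted T-cell data) times a
  lognormal jitter `exp(σ·z)`, σ = 0.3 by default, giving realistic
  between-sample spread. Default polarization 0.01 with 1,000 clones
  yields evenness ≈ 0.3–0.95 across compartments, spanning the polarized
  and even regimes.
- **Counts**: `depth = 0` (default) is the sampling-noise-free surface —
  expected frequencies quantized deterministically at 10⁶ total reads
  with a floor of one read per clone (counts must be positive integers
  and frequencies are count-derived; uniform repertoires stay exactly
  uniform). `depth > 0` draws counts multinomially at depth reads per
  clone; clones drawn zero times are dropped, as in real sequencing.
- **Persistence**: the t24 repertoire contains exactly
  `round(ρ·n_clones)` clone keys of its t0 partner (fresh frequencies),
  the remainder freshly generated and kept disjoint from the t0 key set,
  so measured persistence equals ρ exactly at depth 0 and equal sizes.
  Under multinomial sampling, dropout of tail clones biases measured
  persistence below ρ when polarization is heavy — the ±2-percentage-
  point recovery guarantee is tested at mild polarization where dropout
  is negligible; the bias at heavy polarization is a real measurement
  phenomenon, not a defect.
- **Publicity**: a seed-derived pool of public clones; each repertoire
  fills `round(rate · free slots)` slots from the pool (default pool
  200, rate 0.05), and freshly generated private clones are rejected on
  collision with the pool, so publicity is injected, never accidental.
- **CDR3s**: uniform length in 8–20, anchored C…F, uniform interior —
  realistic enough for k-mer and database-matching plumbing. Random
  CDR3s are almost never within edit distance 1 of one another, so LD-1
  networks on synthetic cohorts are nearly edgeless; network
  construction is validated on dense low-diversity fixtures instead.
- **Determinism**: one seed feeds a `SeedSequence` hierarchy keyed by
  (arm, patient, subpopulation), so adding patients or samples never
  perturbs other samples' draws, and emitted files are byte-identical
  across runs.
- **Defaults not fixed by the design** (n_clones = 1,000 per repertoire,
  polarization 0.01, persistence 0.2, pool 200, rate 0.05) are
  desk-scale choices: 1,000 clones is the order of the smaller sorted-
  subpopulation repertoires, a 20% persistence fraction sits inside the
  range observed for memory compartments, and the full default pipeline
  (168 samples, every stage twice for the determinism check) runs in a
  few minutes on one CPU.

What passing tests on synthetic cohorts do **not** show: recovery of any
real cohort's values. The generator has no clonal lineage structure, no
shared antigen-driven convergence (public clones are injected, not
emergent), no compartment-specific V/J usage, and no sequencing-error
model. It demonstrates that the estimators measure what they claim on
data whose ground truth is known.

## Numerical and degenerate-input conventions

- Undefined correlations (zero variance, < 3 complete pairs) are NaN
  flags, never exceptions.
- `1 − r` distances are clipped at 0 only for negative values within
  1e-9 (round-off above r = 1); genuinely negative distances still
  error.
- Top-N and highly-shared orderings break ties deterministically
  (frequency/sharing count, then lexicographic key).
- Empty repertoires error in persistence and matching (the mean in the
  denominator is undefined at zero clones).
- Pipeline outputs contain no timestamps or absolute paths; manifests
  record the configuration, seed and package version, so identical
  (config, seed) pairs produce byte-identical output trees.

## Known limitations

- Exact Wilcoxon p-values are only available for small tie-free samples;
  depth-0 synthetic cohorts produce heavy ties in count-derived
  statistics (e.g. n_clones is constant), so some paired contrasts are
  degenerate by construction.
- The LD-1 hash join holds for distance exactly 1 on distinct strings;
  it is not a general edit-distance index.
- Database matching is exact-string only; no biochemical similarity, no
  fuzzy matching, and results are tied to the supplied snapshot.
- Evenness-profile correlations on nearly-uniform repertoires are
  numerically unstable (profiles nearly constant); the NaN flagging
  makes this visible rather than hiding it.
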
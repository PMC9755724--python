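# Methods

This note documents the models, conventions, and design choices behind
`exonevo`, and what the simulation-based tests do and do not establish
about real data.

## Coordinates and formats

All analysis is at the protein (amino-acid) level: exon intervals are
0-based, half-open coordinates on the protein sequence, and every size is
in aa. Exon labels are opaque tokens — "4a", "4a-L", "6p" carry no parsed
meaning; ordering comes from coordinates. Unannotated inter-exon residues
are warnings, not errors, because exon assignment is legitimately
uncertain in distant lineages (e.g. jawless fishes). FASTA headers carry
optional `species=…;accession=…` metadata after the record id, and FASTA
round-trips are exact.

## Alignment model and percentage conventions

Pairwise alignment is global Needleman–Wunsch with an affine gap model: a
gap of length *L* costs `gap_open + (L−1)·gap_extend`, with defaults
BLOSUM62, `gap_open = 10`, `gap_extend = 0.5`, and **free end gaps** — the
published defaults of the standard pairwise global-alignment services, so
numbers computed here are comparable with those. The DP engine is
biopython's `PairwiseAligner` configured to exactly this model; the test
suite checks it against an independent brute-force enumeration of *all*
global alignments on short pairs (exact score agreement on 200 random
pairs of length ≤ 6).

Percentage conventions matter because MSA tools define identity
differently. Here:

- identity% = identical columns / **total alignment columns** (gap columns
  included) × 100;
- similarity% adds columns whose residue pair has a positive
  substitution score;
- `max_window_identity` is the best identity over any contiguous window of
  30 columns (one full-length window if the alignment is shorter), in
  percent.

`X` is scored straight from the matrix, no special-casing. Traceback is
the aligner's first optimal path — deterministic for fixed inputs, so
every table is bit-reproducible. Identity matrices align each unordered
pair once and mirror the value, making them exactly symmetric.

## Homology significance

A pair is called **significant** iff identity ≥ 20% *and*
`max_window_identity` ≥ 40%. The 20% floor is the conventional noise
threshold for protein identity at these lengths (random 250 aa pairs align
at < 20% identity, which the tests confirm empirically); the window
criterion operationalizes "scattered identity without contiguous
well-matching areas" as a rejection reason. The 40%/30-column knobs are
exposed as parameters: no principled derivation exists for them, they are
a documented operationalization, and the call is monotone in both
statistics by construction.

## Big-exon discovery and classification

Discovery anchors on the conserved exons flanking the insert locus
(exons 4 and 5 in tau; configurable labels). The **full** target and
reference sequences are aligned — not mini-alignments of the short anchor
exons, which are unstable when diverged — and the reference coordinates
*end of left anchor* and *start of right anchor* are projected through
alignment columns onto the target. A boundary landing on a target gap
snaps toward the candidate's interior, which can only shrink the call
(conservative). `anchor_confidence` is the identity fraction over the 30
columns outside each projection.

Length bands: none < 150 aa ≤ **4a** < 335 aa ≤ **4a-L**. The edges sit in
the empty gaps between the observed size clusters (4a observed 208–320 aa;
4a-L observed 347–400 aa) and are configurable. 4a-L is treated as a
longer variant of the same locus (human 4a-L = 4a + a 104 aa extension),
so no 4a-vs-4a-L sub-region alignment is attempted.

## Distances and trees

Distance is the plain complement `d = 100 − identity` (symmetrized), with
no multiple-hit correction: the trees are descriptive overviews, and at
big-exon identities near the noise floor a Poisson/Kimura correction
diverges while the complement stays bounded. Trees are Saitou–Nei
neighbor joining (scikit-bio), negative branch lengths clamped to zero.
On additive matrices NJ provably recovers topology and branch lengths,
which the tests verify exactly on random 5–8-taxon trees; identity-derived
distances from real data are *not* additive, so real trees are
qualitative.

## The simulator

`simulate_family` evolves an ordered multi-region protein along a Newick
tree:

- **Substitutions** follow a 20-state Jukes–Cantor-like chain: along a
  branch of length *t*, a site in a region with rate *r* changes with
  probability `(19/20)(1 − e^(−r·t))` to a uniformly chosen different
  residue. This multiple-hit parameterization gives the exact closed form
  `P(identical) = 1/20 + (19/20)·e^(−r·(t1+t2))` for two leaves at path
  lengths t1, t2 from their common ancestor; the tests check simulated
  identities against it within 3 Monte-Carlo standard errors. A uniform
  replacement model (rather than a BLOSUM-conditioned one) is deliberate:
  percent identity, the statistic of interest, is composition-insensitive,
  and uniformity is what admits the closed form.
- **Indels**: event count ~ Poisson(rate · L · t), insertion/deletion with
  equal probability, geometric lengths (default p = 0.3, mean ~3.3 aa),
  positions uniform *within a single region* — indels never straddle
  region boundaries, keeping per-region ground truth well-defined. This is
  a simplification relative to real evolution.
- **Exonization events** insert a fresh region of length
  `round(Normal(μ, σ))` and uniform random composition after a named
  region on a named branch, inherited by all descendants. Uniform
  composition makes inserts from different events share no homology
  (cross-insert identity ≈ noise floor) — precisely the signature of
  independent exonization the pipeline is meant to detect.

Everything is reproducible from the config seed: identical configs give
byte-identical sequences, maps, and truth.

### Presets

- `primate_4a` — six taxa, leaf depths 0.02–0.13; rates N-terminal 0.3,
  linker 0.2, big exon 0.8, MTBD 0.05; big-exon identities stay > 85%.
- `vertebrate_4a` — six-taxon star, leaf depth 1.3; rates 0.25 / 0.2 /
  0.7 / 0.08; big-exon identities fall below 30% while the MTBD-like
  region stays above 70% — the deep-vertebrate regime.
- `jawless` — three deep taxa, no big exon, fast N-terminal.
- `exonization_recovery` — two balanced clades at leaf depth 1.0 (the
  canonical depth-1 condition for this rate grid), regions N-terminal
  170 aa @ 0.05 and MTBD 250 aa @ 0.01, no indels, one exonization event
  (μ = 251, σ = 5, rate 0.30) on one clade's stem branch. Used for
  parameter-recovery experiments: rate/identity Spearman correlation,
  detection sensitivity/specificity, and boundary error.

Rates are chosen from the closed form so the regimes are separated by
several standard errors at the given region lengths, making the
qualitative assertions (orderings, thresholds) deterministic in practice
across seeds.

### What passing simulations do and do not show

The generator emulates per-region rate heterogeneity, indels, and
lineage-specific insertion — enough to exercise every pipeline stage with
known truth. It does **not** emulate selection, codon structure,
composition bias, repeat expansion, alternative splicing within a genome,
or annotation error. Perfect recovery on clean simulations therefore
validates the *machinery* (projection arithmetic, classification bands,
matrix/tree construction), not the biological interpretation of any real
alignment; on real data, anchor quality and annotation correctness
dominate.

## The bundled survey

`exonevo.data/mapt_survey.tsv` is a small curated table of cross-species
MAPT region identities (vs the human reference carrying the matching
big-exon variant) and region sizes, used as reference *inputs* for the
conservation-ratio summaries. Species analyzed under both big-exon
variants appear once per variant; summaries use the variant actually
analyzed for each species, preferring the 4a-L entry where both exist
(this matters for carp, which has a 4a entry at 15% and a 4a-L entry at
18%). The headline summaries computed from it: vertebrate 4a/4a-L
conservation relative to the MTBD = 26.5% → 27; mammal big-exon mean =
58.3% → 58; human 4a-L extension = 104 aa.

## Numerical choices and degenerate inputs

- Empty sequences cannot be aligned (error); single-record matrices and
  < 3-leaf NJ are errors.
- `conservation_ratio` reports the unrounded value alongside the
  nearest-integer form, and rejects a zero denominator mean.
- Regions a species lacks are skipped with a log entry, never zero-filled,
  so tables mirror genuinely absent variants as absent rows.
- Ranking ties in similarity scans break by score, then identity, then
  record id — fully deterministic.
- Report bundles omit timestamps, so a rerun with the same config and seed
  is byte-identical.

## Problem sizes

Default experiment sizes are desk-scale: ~770 aa proteins, families of
4–6 taxa, 20-seed replication for recovery experiments, 200 enumeration
pairs and 50 random trees for the oracle checks. The full test suite and
the acceptance script each complete in well under a minute on one CPU.

## Known limitations

- Identity-complement distances are not additive; NJ trees from real
  identity matrices are qualitative overviews only.
- The discovery algorithm assumes exactly one big-exon locus between the
  two anchors; tandem or nested inserts would be merged into one call.
- The significance thresholds (20% / 40%-in-30) are conventions, not
  fitted quantities.
- The exon-map TSV is this package's exchange format; users transcribing
  annotations from genome browsers must convert to protein coordinates
  themselves (`validate_annotation` checks the result).
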
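# Methods

This note documents the models and procedures implemented in `ptmbgc`,
the parameters that matter, the numerical conventions, and what the
synthetic benchmarks do and do not demonstrate.

## Anchored-synteny BGC mining

A PTM BGC is detected as a neighborhood around an **anchor gene**, the
ikaB-like phytoene-desaturase/dehydrogenase homolog of the reference
cluster. The procedure:

1. **Anchor search.** Every protein in the genome is aligned to the
   reference anchor by Smith–Waterman (BLOSUM62, gap open 11 / extend 1).
   Hits with E ≤ `anchor_max_e` (default 1e-6) and bit score ≥
   `anchor_min_bits` (default 1000) become anchors; each seeds its own
   neighborhood, so duplicated anchors yield multiple overlapping calls
   (merged only in reporting, never in calling).
2. **Neighborhood extraction.** The `window_radius` (default 15) genes on
   each side of the anchor by gene index, on the anchor's contig, strand
   ignored. Windows truncated by contig ends are flagged but evaluated
   under the same rule — draft genomes are fragmented, and the calling
   threshold is already conservative.
3. **Synteny mapping.** Bidirectional best hits between the reference
   cluster's genes and the window genes. A pair **qualifies** when its
   E-value is strictly below `synteny_max_e` (default 1e-6).
4. **Calling.** The neighborhood is an orthologous PTM BGC iff it has at
   least `min_syntenic` (default 3) qualifying pairs.

Design choices that were genuinely open:

* A *syntenic homolog* is defined purely as a BBH inside the window; gene
  order and strand are **not** required. This is the most permissive
  reading consistent with the procedure's description; a colinearity
  column is reported for inspection but never filters.
* The anchor's own BBH counts toward the three-homolog minimum (it is
  itself a homolog of a reference gene). Users who want it excluded can
  raise `min_syntenic`.

## Alignment statistics

Alignment is exact Smith–Waterman/Needleman–Wunsch (through Biopython's C
pairwise aligner), not a heuristic seeded search; on desk-scale proteomes
this is affordable and exactly reproducible. Raw scores are converted by
the Karlin–Altschul formulae

```
bits = (λ·S − ln K) / ln 2        E = m · n · 2^(−bits)
```

with gapped-BLOSUM62 constants λ = 0.267, K = 0.041, m the query length
and n the total residue count of the searched set. There is no
composition-based adjustment and no finite-size length correction, so bit
scores do **not** numerically match NCBI BLAST; all thresholds are plain
config values precisely so they can be re-calibrated against another
scorer. The unknown residue `X` (also used for masked internal stops)
scores 0 against everything. BBH ties on equal raw score resolve to the
lexicographically smaller subject id.

The protocol's 1000-bit anchor threshold is unusually high for a ~500-aa
protein; this implementation honors that value as its default and
sizes the synthetic anchor exemplar (~800 aa) so the threshold is
reachable. Real-data use may require lowering `anchor_min_bits` to match
the scorer in use.

## Enzyme-family classification

Cluster genes are labeled by **nearest reference**: the best-scoring
labeled exemplar that passes E ≤ 1e-6 (the same stringency as synteny
mapping — one consistent cutoff) assigns its family; each gene gets at
most one label, and the content matrix records presence/absence only, so
paralogs do not inflate cells. A hit landing in the dehydrogenase
super-family is refined to DH1/DH2/DH3 by best bit score, ties broken by
percent identity and then the fixed order DH1 < DH2 < DH3.

Profile HMMs were deliberately not used: the repertoire is small, the
source analysis was itself BBH-based, and nearest-reference keeps the
method free of external databases. The bundled references are *synthetic
exemplars* (see below); real-data use requires swapping in curated
references, because no sequence-level boundary between DH1/DH2/DH3 is
established in the literature — the subfamily references here are
operational stand-ins.

## Chemotype prediction

The ring rules are correlations over observed BGCs, applied in order:
no DH1 → undetermined (not an error — the rules are not a complete map);
DH1+DH2+OxR → 5-5-6 with a secondary 5-5 (producers of the three-ring
system can additionally make the two-ring compound); DH1+DH2 → 5-5;
DH1+OxR → 5-6-5; DH1 alone → 5. DH3 has no known chemical consequence and
never alters the call; its presence is noted. Tailoring: SD ⇒ C-4
hydroxylation, CYP450 ⇒ epoxidation.

Masses: nominal mode uses integer atomic masses (C=12, H=1, N=14, O=16);
monoisotopic mode exact isotope masses (cross-checked against pyteomics in
the tests). The [M−H]⁻ ion is neutral mass − 1 (nominal) or − 1.00728
(monoisotopic). Nominal is the default for ion matching because SIE traces
are extracted at unit-resolution values. The bundled compound set is
dihydromaltophilin C29H40N2O6 and its formula-level derivatives
(−H2 → 509; −H2O → xanthobaccin C, 493; −H2O−H2 → FI-3, 491); the
formulas come from the compound literature and are validated against the
nominal SIE ion values. Only the formula-level −H2 rule is implemented for the
desaturated analog; the position of the extra unsaturation is not encoded.

## Phylogeny

Marker genes: an rpoB-like RNA-polymerase β homolog (species marker — it
resolves *Streptomyces* better than 16S) and the ikaA-like PKS/NRPS (BGC
marker), extracted as the best hit at E ≤ 1e-8 with bit-score floors 200
and 4000 respectively; absence is a logged warning, not an error.

Tree building is deliberately a deterministic distance pipeline rather
than Bayesian or ML inference: progressive alignment (UPGMA guide tree
from pairwise p-distances, then profile–profile global alignment with
affine gaps; numba-accelerated DP), trimming of columns with > 50% gaps
(the trimming rule is this package's choice; none is established),
pairwise-deleted p or Poisson (−ln(1−p)) distances, neighbor joining with
negative branch lengths clamped to zero and ties joined lowest-index
first, outgroup rooting at the midpoint of the outgroup's pendant edge
(idempotent), and nonparametric bootstrap (column resampling, seeded).
Supports are **bootstrap percentages**, stored under their own name so
they cannot be conflated with posterior probabilities. Because alignment
and trimming choices differ between analyses, topology
agreement with previously reported trees on real data is not asserted anywhere.

## Gain/loss reconstruction

Each family is a binary character on the rooted species tree,
reconstructed by Fitch small parsimony (Sankoff-style DP). Branches where
the child state differs from the parent emit events: 0→1 = recruitment
(R), 1→0 = loss (L). Ties at the root resolve toward absence — the
narrative bias is toward later recruitment — and this is config-flippable
(`root_tie_state`). When multiple most-parsimonious labelings exist, one
deterministic labeling (prefer the parent's state at internal ties,
preorder) is reported together with the count of optima, so ambiguity is
visible rather than hidden.

HGT screening is intentionally a lightweight heuristic matched to the
strength of the claim it supports: a taxon is flagged when its nearest
neighbor (topological distance, ties to the smallest label) in the gene
tree belongs to a different group (e.g., phylum) than its nearest
neighbor in the species tree. It is not a reconciliation method and will
miss transfers between near relatives.

Genome reduction: a genome is flagged when its length is strictly below
mean − SD of the genus distribution (defaults 8.3 − 1.1 = 7.2 Mbp, from
395 *Streptomyces* genomes). The comparison uses a 1e-9 Mbp guard so a
genome exactly on the threshold is never flagged through floating-point
representation of the difference.

## Synthetic data: what it emulates, and what it does not

The generator produces a clade of genomes that exercises every stage with
known truth:

* **Tree:** Yule process, unit birth rate, seeded; leaves t1..tn,
  internal nodes n1.. in preorder (these ids are the event-script
  addresses).
* **Sequence evolution:** substitutions only. Counts are
  Poisson(L·rate·t); positions uniform with replacement; replacements
  drawn ∝ 2^(S/2) over the BLOSUM62 row, identity excluded. No indels, no
  rate heterogeneity, no codon structure.
* **Exemplars:** drawn once from a fixed internal seed — ~3000-aa
  PKS/NRPS and ~800-aa anchor so the 4000- and 1000-bit
  thresholds are exercisable, ~1200-aa rpoB-like marker, 300–400-aa
  tailoring enzymes. The three DH exemplars descend from a common
  ancestor (0.45 expected substitutions/site per side; DH3 from the DH2
  side at 0.18), which keeps DH1/DH2 similarity safely below the anchor
  threshold while leaving true homologs detectable, and makes the
  subfamily assignment a genuinely graded (not trivial) problem.
* **Events:** scripted per branch. Gains insert a lightly diverged family
  exemplar; losses delete the family (erroring if absent on that
  lineage); a DH2 duplication models the documented DH2→DH3 expansion —
  because a substitution-only simulator has no selection to drive a copy
  toward a subfamily, the duplicate is seeded from the DH3 exemplar and
  recorded in truth as a DH3 recruitment via duplication.
* **Genomes:** one contig; 150–450-aa uniform-random decoys (default 40)
  with the BGC inserted contiguously at a chosen index (default 20) and
  the rpoB-like marker appended; total lengths drawn in 6.5–9.5 Mbp so
  the reduction flag has both outcomes. Uniform-random decoys make the
  probability of a decoy passing E ≤ 1e-6 negligible, which is what makes
  the 0%-false-positive benchmark clean — real genomes contain genuine
  distant homologs and will not be this clean.
* **Ions:** one Gaussian-jittered [M−H]⁻ ion per bundled compound
  (default SD 0.1 Da vs a 0.5 Da matching tolerance).

Default study conditions: 8 taxa, rate 0.1 substitutions/site per unit
branch length, and the event script (a tailoring loss, a DH2→DH3
duplication, an OxR loss on three pendant branches) emulating the kinds
of branch events the reconstruction is meant to recover. Benchmarks in
the test suite use 4–6-taxa instances of these conditions so the full
suite stays in the minutes range on one CPU.

Passing the synthetic benchmarks demonstrates internal correctness
(recall/precision against implanted truth, parsimony optimality,
NJ consistency, recovery of scripted events) — it does not demonstrate
performance on real genomes, where annotation quality, genuine paralogy,
fragmented assemblies and compositional bias all bite.

## Numerical conventions and degenerate inputs

* Coordinates are 0-based half-open internally; GenBank's 1-based
  inclusive on disk. Compound (join) locations use the overall span and
  the spliced translation. CDS without a translation qualifier are
  translated with the bacterial code; trailing stop dropped, internal
  stops kept as `X` so pseudogenes still occupy a window slot.
* Empty alignments, empty hit lists and unassigned genes are valid
  results, not errors; absent markers warn.
* Newick output is canonical (`%g` branch lengths, supports as internal
  labels) and is its own parser's fixed point, so write→read→write is
  byte-stable.
* All randomness flows from explicit seeds (one `SimConfig.seed` per
  dataset; spawned substreams per stage); equal config ⇒ byte-identical
  outputs, which the report manifest checksums make checkable.

## Known limitations

* Bit scores are not BLAST-comparable (documented above); literature
  threshold values carry over only in spirit when a different scorer is
  used.
* Nearest-reference classification degrades for families whose diversity
  is not represented by the bundled single exemplar per family.
* The ring rules are correlative; a determinate prediction is a
  hypothesis, not an assay.
* The HGT screen detects only transfers that move a taxon's gene-tree
  neighborhood across group boundaries.
* No indel simulation: alignment columns in synthetic benchmarks are
  structurally trivial, so the progressive aligner's gap handling is
  exercised mainly by the engineered-indel unit tests, not the
  simulations.
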
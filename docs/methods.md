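# Methods

This note records the models, conventions and parameter choices behind
`tprfam`, and what the synthetic benchmarks do and do not establish.

## Degenerate-consensus scanning

A consensus pattern is parsed into an ordered element list: bracketed
residue classes (`[WLF]` or `(G/A/T)`) are *key sites*; bare letters are
literal constrained positions that are checked but not counted as key
sites; `X(n)` (protein) / `N(n)` (DNA) are fixed unconstrained runs; and
`N(a-b)` is a variable gap. The TPR consensus parses to 8 key sites over a
fixed 29-aa window (8 constrained + 21 wildcard positions); the ISRE
consensus to 3 key classes, 8 literal GAAA-core positions and a 1–2 nt
gap (span 12–13 nt).

Two calling modes reflect how the two motifs are used in practice:

* **Protein (TPR):** a sliding window is a candidate when strictly more
  than `threshold` key sites match (default 4, i.e. ≥ 5 of 8). Overlapping
  candidates are resolved greedily — keep the highest key-site count, ties
  to the leftmost start, repeat — because TPR units are tandem,
  non-overlapping repeat units. The reported interval is the 29-aa
  consensus footprint, the only extent the consensus itself defines.
  Matches at non-key constrained positions are counted and reported but
  never filtered on; an optional secondary threshold exists and defaults
  to off, since no principled value for "conservation at the other sites"
  is available.
* **DNA (ISRE):** a hit requires *every* constrained position to match for
  some gap choice (the element is short and biologically defined by its
  full consensus, not a partial-match score). Gap choices at the same
  start collapse to the shortest span. Both strands are scanned by
  default; reverse-strand hits are reported in forward-strand coordinates
  with strand `-`. Orientation matters biologically (family promoters
  typically carry their ISREs in one orientation), so it is reported, and
  forward-only scanning is a flag.

Coordinates are 0-based half-open on the forward strand everywhere.
Ambiguity symbols never match a constrained position (`N` in DNA, `X` in
protein); they pass wildcards. `brute_force_scan` re-implements both modes
as a literal enumeration over every position × gap assignment with no
shortcuts, and exists purely as the oracle against which the production
scanners are compared in tests.

## Promoter annotation

`upstream_distance = tss_index − hit.start`: distances are measured from
the **motif start** to the TSS. The figure-style per-motif distances this
mirrors do not state an endpoint convention, so one had to be fixed; motif
start is the conventional anchor. Proximal means
`0 < distance ≤ 200 bp` (the arrangement typical of these promoters);
the cutoff is a parameter. The full supplied sequence is scanned — no
implicit truncation — and hits downstream of the TSS carry negative
distances and are never proximal.

## Distances, neighbor joining, bootstrap

Identity between aligned rows is computed over columns where neither row
has a gap (pairwise gap deletion); distance is `1 − identity/100`
(p-distance). No model correction is offered: the upstream alignment tool
this replaces does not document one, so the package states its convention
rather than guessing another.

`nj_tree` is standard Saitou–Nei agglomeration with two determinism
guarantees: Q-matrix ties break toward the lexicographically smallest pair
of cluster tags (a cluster's tag is its smallest member label), and
negative branch-length estimates are clamped to zero with the deficit
transferred to the sibling edge (standard practice). On an additive matrix
the output reproduces the generating tree exactly (RF = 0, path lengths to
1e-9), which the suite verifies on random trees of 4–12 taxa; topology is
also cross-checked against R's `ape::nj` on a perturbed matrix.

Bootstrap resamples alignment columns with replacement; support of each
bipartition in the point-estimate tree is the percentage of replicate
trees containing it, attached as internal-node labels. Everything is
driven by a single seeded generator and is exactly reproducible.

**Membership classification.** The tree is rooted from the outgroup; the
family is the smallest clade containing every reference sequence, and a
candidate is a member iff it lies inside it. This makes a candidate
attached on the edge between family and outgroup a non-member (basal to
the family), which is the conservative reading. A non-monophyletic
outgroup triggers a warning; classification proceeds by the same
reference-clade rule, which is insensitive to strays on the outgroup side.
Subgroups are the maximal same-lineage monophyletic groups after outgroup
rooting, labelled `<lineage>_<ordinal>` in traversal order — under purely
post-split duplication they coincide with the lineages; a duplication
predating a split correctly yields two subgroups of that lineage.

## Synteny

Colinearity between two locus profiles is `(shared, ordered_shared)`:
the size of the gene-name intersection (names disambiguated by occurrence
index, so a duplicated name counts at most its multiplicity) and the
longest common subsequence of the two shared-name orderings. LCS is the
minimal order-aware statistic: it is symmetric, invariant under jointly
reversing both profiles, and loses at most one unit per adjacent
transposition (`ordered_shared ≥ n − k` after `k` swaps), all of which are
property-tested. Orientation is deliberately excluded from colinearity and
analysed only for focal-gene runs. Conservation classes label each
surrounding gene by its lineage-presence set (`all_lineages`,
`<lineage>_only`, or the joined lineage list); the classes partition the
observed names. Contiguity reports the non-focal genes lying strictly
between the first and last focal gene. The ~10-Mb flanking window that
real inputs would be cut to is a property of input preparation, not
enforced here.

## Gene structure

The canonical family gene has two exons with a 5-nt coding first exon
(ATG + two nucleotides of codon 2). `canonical_first_exon` measures the
coding portion of the transcription-order first exon on either strand;
mirroring a model to the opposite strand preserves every call. Exon-count
classes are literal up to four (`one_exon` … `four_exon`) with `many_exon`
for ≥ 5; the raw count is always reported alongside so an alternative
binning of the residual category remains recoverable. A retrogene
candidate is an intronless gene whose locus shows no conserved neighbours
(or has no locus profile at all); an intronless gene that retains locus
synteny is left unflagged, since segmental duplication explains it better.

## The synthetic-data generator

The generator's purpose is *known truth*, not sequence realism.

* **Planted TPR proteins:** uniform-random background; each planted 29-aa
  window instantiates exactly the requested number of satisfied key sites
  (matched sites drawn from the class, unmatched from its complement).
  Whole-background rejection sampling guarantees that no window other than
  a planted one reaches the calling threshold, so scanner output equals
  planted truth exactly — that guarantee is what makes the
  sensitivity-1.0 / false-call-0.0 benchmark meaningful.
* **Planted ISRE promoters:** exact consensus instantiations at requested
  TSS distances and orientations; rejection sampling removes accidental
  background consensus matches on either strand.
* **Family evolution:** a genome-level birth–death process along a
  species tree of four lineages (fish, amphibian, bird/reptile, mammal;
  two species each; terminal branches 0.1, inter-lineage stems 0.35–0.5
  expected substitutions/site). Duplications copy a gene in place —
  tandem, same orientation — with small probabilities of translocation to
  a fresh chromosome (0.05) or retrotransposition (0.03: the copy moves to
  an unlinked locus and loses its introns). Losses delete. Sequences
  evolve by per-site Poisson substitution, uniform over the other 19
  residues — clade separation, not biochemical realism, is what the
  benchmarks need. Default rates: duplication 1.5, loss 0.2 per gene per
  unit branch length, restricted by default to branches wholly within one
  lineage (`duplication_scope="lineage"`, the lineage-specific-expansion
  regime); `"terminal"` gives purely species-specific expansion and
  `"all"` permits pre-split duplications. Two outgroup sequences (and
  optional decoy candidates) evolve from a separate branch of length 1.2.
  Flanking genes have per-lineage retention (0.8, with the five core
  markers always retained), and orders are shuffled by Poisson(1) adjacent
  transpositions that never break the focal cluster. Every family gene
  gets the canonical two-exon model except retrocopies (intronless). If
  any species ends with zero genes the replicate is regenerated from a
  spawned sub-seed and the attempt count recorded.
* **Root protein length 1000 aa.** The clean-signal benchmarks require
  that distance noise not obscure the (long) inter-lineage stems. With
  uniform-model p-distances the deep splits sit in the saturating range,
  and at a few hundred columns the residual noise misplaces a deep branch
  in ~5% of replicates — the neighbor-joining topology then matches
  `ape::nj` exactly, i.e. it is a property of the data, not the
  implementation. 1000 columns brings lineage-monophyly recovery to
  ~96–97% of replicates while keeping a replicate under ~20 ms.

Fixed seed ⇒ byte-identical outputs (FASTA, Newick, lineage/profiles TSV,
GFF3, truth JSON), which the suite checks by comparing file bytes.

## What the benchmarks show — and don't

Passing the planted-motif suites shows the scanners implement the stated
rules exactly on backgrounds engineered to be clean; real proteomes
contain near-threshold windows whose biological status no consensus rule
can settle. The phylogenetic benchmarks operate in a clean-signal regime
(long stems, gap-free equal-length alignments, uniform substitution);
they validate the algorithmics and the classification logic, not
robustness to alignment error, rate heterogeneity or long-branch
attraction. Synteny profiles are small and noise-free compared to real
annotation pipelines. Problem sizes in the acceptance script (hundreds of
sequences, 100 family replicates, 200 additive matrices) were chosen as
the package's own benchmark conditions.

## Known limitations

* Alignment computation is out of scope; aligned input is consumed, and a
  gap-free "aligner" exists only for equal-length simulated sequences.
* p-distance is the only distance model; no ML/Bayesian trees.
* The motif scanner is a consensus-rule engine, not a PWM/HMM; no
  genome-scale performance work.
* Ambiguity handling is strict by design (N/X never match), which
  undercalls on low-quality sequence.
* The simulator has no indels, no codon structure, no whole-genome
  duplication, and its flanking-gene model is presence/order only.
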
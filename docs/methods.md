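# Methods

## Architecture curation

A domain architecture is the N→C ordered list of conserved domains in a
protein, written as a key such as `Trypsin|ShK|ShK`.  Curation from raw
hmmscan per-domain tables proceeds in four steps.

**Selection.**  A protein enters the tryptome when at least one hit to a
trypsin family (default `{Trypsin, Trypsin_2}`) has full-sequence E-value
≤ `protein_evalue_max` (default 1e−05).  The full-sequence E-value (not the
per-domain one) gates selection because the cutoff is a statement about the
protein, not about a single placement; the per-domain filter below handles
placements.  An exclusion list stands in for manual curation steps
(pseudogene removal, duplicate gene models, transcript correction) that are
inherently external to an automated pipeline.

**Per-domain filter.**  All hits — trypsin and associated — must have an
independent (domain-specific) E-value ≤ `domain_ievalue_max` (default
0.05) to be placed.

**Merging of partial hits.**  Profile matches to a single real domain are
sometimes reported as several partial hits.  Two same-family hits are
treated as parts of one domain when they are disjoint on the protein and
their profile intervals are complementary: jointly they cover more of the
profile than either part alone.  Chains of partials are built in protein
order, and a hit extends a chain only if it also enlarges the chain's
*cumulative* profile coverage — without this, the first partial of a second
same-family domain (which restarts near the profile start) would be
absorbed into the previous domain's chain.  A merged domain spans
min(start)…max(end) and takes the minimum E-value of its parts.

**Overlap resolution.**  Domains are accepted greedily in ascending
E-value (ties: smaller start, family name, end — fully deterministic);
a candidate is dropped when it overlaps an accepted domain by more than
`overlap_frac_max` (default 0.20) of the *shorter* of the two.  The
shorter-domain denominator is symmetric and standard in domain-annotation
practice; greedy elimination makes the outcome independent of input order
and idempotent.  Setting `overlap_frac_max` to 0 degenerates to
"one domain per overlapping cluster".

Coordinates are 1-based inclusive amino acids throughout, as printed by
HMMER.

## Census

`classify_tryptome` partitions architectures by the presence of at least
one non-trypsin placed domain.  `domain_abundance` compares, per associated
family, the number of instances inside the tryptome with the number in the
rest of the predicted proteome; the ≥ 10% ("high abundance") and ≥ 15%
("strong association") flags are descriptive thresholds, not tests — an
optional hypergeometric enrichment p-value can be attached but is off by
default.  Architecture identity for cross-taxon sharing is the exact
ordered family sequence with multiplicity, because a re-arrangement of the
same families is a genuinely different protein plan; a set-of-families mode
exists for sensitivity checks.

## Feature annotation

**Catalytic triad.**  Serine-protease activity requires His-57, Asp-102 and
Ser-195 (chymotrypsin numbering).  The three alignment columns are located
by walking the ungapped coordinates of a user-named reference sequence; a
protein passes a site only with the exact residue letter
(case-insensitive), so conservative substitutions and gaps count as losses.
This is deliberately strict: the triad chemistry tolerates no substitution
at these sites.

**Secretion/membrane flags.**  SignalP v4.1 and TMHMM v2.0 short-format
tables are consumed as-is (column 10 Y/N decision; `PredHel=N`), never
recomputed.  Proteins missing from a table default to `False` with a
warning rather than an abort.

**Exon structure.**  A placed domain's amino-acid span is projected into
transcript coding coordinates ((start−1)·3+1 … end·3) and intersected with
the CDS segments in transcription order (reverse-strand genes walk their
segments high→low, so mirrored genes give identical counts).  The exon
count is the number of CDS segments holding more than `overhang_nt`
(default 10) nucleotides of the domain's coding sequence, never below 1:
a domain poking ≤ 10 nt across a junction is called single-exon.  Counts
are monotone non-increasing in `overhang_nt`.  Intronless genes — exactly
one CDS segment — are flagged as retrotransposition candidates.

## Single-cell co-expression

Expression is presence at ≥ `min_reads` (default 1) raw counts; no
normalisation is applied, matching the very permissive read-count cutoff
this style of census uses.  Over the tagged trypsin gene subset the module
reports the number of expressing cells, the histogram of trypsins per cell,
and per gene the pair (ubiquity, co-expressing cells).  Pearson is the
default correlation over those pairs, with Spearman computed alongside.
Rows may be cells or metacells; the module is agnostic and callers record
which in their provenance log.  Identities that must hold and are tested:
Σₖ k·hist[k] equals total expressed incidences, co_cells ≤ ubiquity per
gene, and raising `min_reads` never adds expressing cells.

## Phylostratigraphy

Features are domain families and `trypsin+X` associations (some protein in
the taxon carries both a trypsin domain and family X).  Under a single-gain
(Dollo) reading the origin of a feature is the MRCA of all taxa possessing
it — a *minimum* age.  Ages are ordinal stratum ranks (edges from the root;
root = 0 = oldest): the input trees carry no calibrated dates, so only rank
comparisons are meaningful.  Losses are the maximal all-absent clades below
the origin; they are mutually disjoint by construction.  Features whose
Dollo reading needs many independent losses can be flagged
(`warn_loss_count`), since repeated independent gain is then an equally
spartan explanation; the module reports, it does not adjudicate.

The age relationship pairs each association's stratum with its partner
domain's stratum and computes a tie-corrected Spearman correlation.  An
association older than its own domain is impossible and raises an error
naming the feature — it signals inconsistent presence data.

## Gene-tree inferences

**Representation clades.**  Because per-group species counts only grow
toward the root, any ancestor of a satisfying clade also satisfies the
criterion; the informative clades — each marking one ancestral gene — are
the *deepest* satisfying ones (no satisfying proper descendant).  They are
mutually disjoint.  "Lineages" are counted as distinct species by default;
a genus mode exists.  Support labels are carried through, never filtered
on.

**Tandem candidates.**  Same-scaffold sister pairs are restricted to
cherries of the focal taxon; the genomic gap is the distance between the
nearest feature ends (0 when overlapping, undefined without coordinates).
Larger single-scaffold clades are reported separately as candidates only.

## Synthetic data

The generators write the same plain-text formats the pipeline reads, plus
truth objects; a fixed `SimSpec` (seed included) yields byte-identical
files.  What they emulate, and what they do not:

* **Hit tables** realise an architecture catalog shaped like a real
  tryptome (trypsin-only dominating at ~0.39, plus ShK/PDZ/MAM/Sushi/SRCR/
  Astacin/WSC/Lustrin combinations, including a triple-trypsin key).
  True E-values sit safely inside the thresholds (log-uniform 1e−30…1e−06);
  decoy hits straddle both thresholds (passing decoys join the planted
  truth key, failing ones must be filtered) and decoy proteins carry only
  above-threshold trypsin hits.  With probability `split_probability`
  (default 0.25) a trypsin domain is emitted as two complementary partials.
  Sequences in the companion FASTA are random letters — only lengths are
  meaningful.
* **Gene models** plant intronless genes and domains overhanging exon
  boundaries by exactly 8 and 11 nt (straddling the 10-nt rule), each
  forward-strand gene mirrored on the reverse strand.  Exon-1 coding length
  301 nt makes those overhangs realisable on codon-aligned spans.
* **Cell matrices** emulate the mode-at-1 trypsins-per-cell shape: ~49% of
  expressing cells are single-trypsin (solo), co-expressing cells draw
  2 + geometric(k) genes (mean 4) weighted by a mildly heavy-tailed gene
  popularity (lognormal σ = 0.35), ~10% of cells are silent, and expressed
  entries get 1 + geometric reads.  The planted ubiquity–co-expression
  correlation (default 0.9) is realised by giving each gene a solo-cell
  count drawn independently (gamma) with variance solved from
  corr(m+s, m) = ρ, where m is the co-expression count; over 100 seeds the
  realised Pearson spans ≈ 0.82–0.95 around the plant.  Truth is the tally
  of the *emitted* matrix, so recount tests are exact.
* **Presence characters** gain at a uniformly chosen node of a random
  binary tree and lose along each lower edge independently (default 0.2),
  cutting off whole subtrees; all-absent features are discarded.
* **Gene trees** build planted same-scaffold cherries as units before
  random joining, so plants are guaranteed sisters and distractor leaves
  cannot create false positives.

None of the generators produce realistic sequence content, read-level
data, alignment uncertainty, or correlated loss — so passing tests certify
the *rules* (thresholds, merging, counting, dating) and not robustness to
real-data noise such as fragmented gene models or mapping artefacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately modest sizes
chosen to exercise every rule boundary: 50–72 proteins per simulated
proteome, 600 cells × 60 genes per matrix (100 seeds for the correlation
recovery), 500 random trees of ≤ 32 leaves for the origin-dating oracle and
≤ 20 leaves for the clade-enumeration oracle, and 200 replicates for the
null age-relationship simulation.  Random streams are per-generator
(`default_rng([seed, stream])`), so changing one stage's draw count never
perturbs another's fixtures.  E-value decoys avoid the exact threshold
values (drawn from (1e−4, 0.045] and [0.06, 10)) so boundary behaviour is
exercised without float-equality ambiguity; the thresholds themselves are
compared with `<=` as stated.

## Known limitations

* The single-gain origin is a minimum age: under lineage loss the MRCA of
  the *surviving* presence taxa can postdate the true gain (recovery is
  ~80–90% at 20% loss on 16-leaf trees), and independent gains are
  conflated with losses by construction.
* The null simulation of the age relationship shows |Spearman| < 0.3 in
  ~85% of 24-pair replicates — the exact sampling variability of a rank
  correlation at that n (sd ≈ 1/√23 ≈ 0.21); claims about "no
  relationship" at this size are qualitative, not sharp.
* Manual curation is modelled only as an exclusion list; the pipeline
  cannot reproduce judgment calls made against transcriptome evidence.
* Architecture sharing across taxa assumes the same Pfam version and
  thresholds were used for every proteome.
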
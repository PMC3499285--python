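# Methods

This note documents the models, conventions and numerical choices behind
`defmine`, and what the synthetic study system does and does not emulate.

## Coordinate and scoring conventions

Declared once and used everywhere: genomic coordinates are 1-based
inclusive (GFF3 convention), with minus-strand features keeping
forward-strand coordinates and transcription-ordered exon lists; peptide
offsets are 0-based. Percent identity is matches over aligned columns,
counting internal gap columns and excluding terminal gaps; coverage is
the aligned span of the query divided by query length. These follow
common BLAST-report reading practice; they are stated explicitly because
the thresholds that depend on them are strict inequalities.

## Discovery

The six-frame scan translates with a plain codon table; any codon
containing a non-ACGT letter becomes `X`, and `X` never matches a motif
cysteine (conservative with ambiguous assemblies). The motif scanner
accepts per-spacer `(min, max)` intervals, defaulting to the fixed
spacing C-X6-C-X4-C-X9-C-X6-C-C; all overlapping matches are reported. A
candidate is a maximal stop-free stretch of one frame containing the
motif, at least `min_orf_aa` residues long. The default floor is 31 —
exactly the motif span — because the motif is the selective signal and a
three-exon locus can truncate the surrounding open stretch to little
more than the motif itself; raise it for stricter screens.

The homology screen is pairwise local alignment (match 2, mismatch −3,
gap open 5, extend 2) of each candidate against every panel entry — a
deliberate choice over wrapping an external search tool, since desk-scale
panels make O(nm) alignment trivial. Classification: `pass` iff identity
> 70 **and** coverage > 50 (strict); `rescued` iff coverage ≤ 50 and
identity ≥ 80; otherwise `fail`. The rescue threshold of 80% is chosen so
that the canonical short-but-similar cases (32%/81% and 42%/86%) are
retained by rule rather than by manual adjudication; rescues are surfaced
as warnings.

Gene models: with a guide cDNA, exons are co-linear exact-match blocks
whose gaps are GT..AG introns within bounds (default 60–10,000 bp; the
bounds are generous and configurable because true intron sizes vary
widely). The chain is found by depth-first search with backtracking over
donor placement, since a maximal exact match can overrun the true donor
when the intron happens to start with the next exon's bases. Without a
guide, 2-exon junctions are enumerated: exon 2 starts at an in-frame
acceptor upstream of the motif, exon 1 is the longest in-frame ATG-led
stop-free stretch ending at a GT donor, and the junction set maximizing
total ORF length wins (ties to the smallest coordinates). A model with no
GT-AG-consistent chain is classified `rejected` with the reason recorded.
Classification: `intact` (≥2 exons, initiator M, no internal stop, motif
present), `three_exon` (same with 3 exons), `partial_psi` (exon-2-only
model with motif but no exon 1), else `rejected`.

## Phylogeny and naming

Pairwise protein alignment uses Biopython's `PairwiseAligner` with the
GONNET1992 matrix, gap open 7 and extension 0.2 (the first gap position
costs the opening penalty); ties resolve to the aligner's deterministic
first traceback. No progressive multiple aligner is re-implemented: the
tree stages accept any pre-made alignment (equal-length records), and the
pipeline treats equal-length inputs as aligned.

JTT distances are maximum-likelihood: the published Jones–Taylor–Thornton
exchangeabilities and frequencies (verified against phangorn's data
object) define a rate matrix normalized to one expected substitution per
site; `P(t)` comes from the symmetrized eigendecomposition, and the
likelihood of the ungapped site-pair counts is maximized by bounded Brent
search on [1e-6, 5] (xatol 1e-8), with estimates capped at 5
substitutions/site. Identical sequences short-circuit to 0. A test
cross-checks the estimator against phangorn's `dist.ml` and against a
grid refinement of the likelihood.

Neighbor joining minimizes the standard Q criterion with ties broken on
the lowest (row, column) index pair for determinism; negative branch
lengths are clamped to zero with the deficit moved to the sibling. The
bootstrap resamples alignment columns with replacement — the random
stream is indexed only by the column draw, so supports are invariant to
taxon input order — builds an NJ tree per replicate, counts bipartitions
(normalized to the side excluding the lexicographically smallest taxon),
and keeps those at or above the collapse threshold (default 50%, i.e.
majority rule; default 1,000 replicates), greedily adding by frequency
when near-threshold conflicts arise. Supports are attached as internal
node labels.

Naming: the candidate takes the number of the reference with the highest
percent identity, written with the pig prefix (pBD*n*). Two references
within 0.5 identity points trigger an explicit ambiguity flag with no
name assigned — such cases were historically adjudicated by hand, and
flagging is safer than guessing. A legacy table keeps established names
(pBD1–4) regardless of the nearest reference, which is still recorded as
evidence; when a bootstrap tree is supplied, the smallest clade joining
the candidate to any reference either confirms or contradicts the
nomination, and the outcome is recorded rather than enforced.

## Synteny

Genes are grouped per chromosome into runs split by gaps larger than
`max_gap` (default 2 Mbp — defensin clusters are sub-megabase, so the
default is permissive) or by an intervening anchor. Clusters take the
anchor pair declared for their chromosome; unanchored clusters are
labeled by their first/last member genes. Genes with chromosome
`unplaced` are never silently placed — they are returned separately with
any inferred position preserved. Cross-species matching normalizes names
to bare numbers (species prefixes stripped) through the legacy mapping
(pig 1/2/3/4 ↔ human 4/1/103/110). Events: `conserved` for one-to-one
cluster maps with identical shared-gene order up to whole-cluster
reversal; `order_change` for same membership in a different order
(reversal never counts); `split` for one-to-many maps, annotated with
direction so that comparing in the other direction yields the mirrored
event; `duplication` when a number recurs within one species;
`unplaced` when a number exists in only one species.

The packaged coordinate fixtures carry real chromosome assignments and
gene orders but synthetic, evenly spaced bp positions (the genome-build
coordinates are not part of the printed record being encoded); the files
say so in their headers. Known discrepancies in the source record are
stored, not resolved: the 57-entry reference list names DEFB132 twice,
and the SSC17 upstream anchor is given as both ZCCHC3 and TRIB3 (the
anchor table stores both candidates and the builder accepts either).

## Variants

Exon-2 SNP calling is column-wise against a local reference: each animal
contributes two haplotypes, either explicitly or as one Sanger-style
trace with IUPAC two-base codes at heterozygous columns. Columns with two
observed alleles become records (major = more frequent, ties to the
reference base); columns with three or more alleles are flagged and
excluded, matching biallelic reporting practice. Consequence annotation
reads the CDS in frame offset 0 — position 1 is the first base of a
codon. That frame is an inference, not a printed fact, but it is the
unique offset consistent with every tabulated variant (the nonsynonymous
contexts and all synonymous positions divisible by 3), and the fixture
test asserts that consistency. MAF is the folded minor-allele count over
non-missing chromosomes (≤ 0.5 by construction).

RFLP design scans both allele contexts with every enzyme's IUPAC site
over all windows overlapping the SNP; an assay is reported exactly when
the overlapping site positions differ between alleles, which is
equivalent (tested) to the two complete digests producing different
fragment patterns. The common case is one cut allele; a SNP that shifts a
site also genotypes. The enzyme table (BstNI CCWGG, EcoRV GATATC, PciI
ACATGT, plus ~30 common 4–6-cutters) is packaged so no external enzyme
database is needed. In-silico PCR reports every product where the
forward primer matches the plus strand and the reverse primer's
complement matches downstream (product length = distance between 5' ends
plus reverse primer length); primers must be ≥ 15 nt.

## Synthetic study system

The generator reproduces the structural features the methods depend on:
2-exon genes (ATG + 19-codon signal exon; 45-codon mature exon containing
exactly one motif; GT..AG introns of 80–800 bp by default), an optional
3-exon configuration whose extra junction falls outside the motif codons
(so the locus remains discoverable in a single genomic frame), random
strands, and uniform-ACGT background rejection-sampled until no motif
window survives outside a planted gene in any frame — a clean negative
control with a calculable false-positive rate (per-window match
probability ≈ (2/64)⁶ under uniform bases, ≪ 1 expected hit per Mbp).
Two generator details exist purely to keep cDNA-guided splice
determination unambiguous at exact-coordinate resolution: exons never
begin with G (so a maximal match cannot extend into a GT intron), and
intron interiors are resampled if they contain an acceptor-mimicking
`AG + exon-prefix` substring.

Populations are unphased diploids: per-SNP alleles drawn binomially at
the specified minor frequency; `ensure_minor` forces at least one copy of
each allele, modeling the fact that a discovery panel only tabulates
sites observed to vary. Default scales are the study conditions: 14
animals for discovery, 35 for genotyping, a 57-entry reference panel.
Panel divergence is Jukes–Cantor-style site-wise substitution at a rate
drawn per entry from the configured range (default 0–30%, which
exercises the 70% identity threshold from both sides); no realistic
substitution model, rate heterogeneity, indels, or breed structure is
simulated. Consequently, passing tests demonstrate correctness of the
algorithms under clean sequence models — exact coordinate recovery, exact
threshold behavior, unbiased frequency estimation — not robustness to
assembly gaps, paralog collapse, alignment error, or real mutational
processes.

Sequence-level fixtures that the printed record does not contain are
synthetic and labeled as such: the exon-2 reference CDS per SNP-table
gene is generated deterministically to satisfy every tabulated constraint
simultaneously (position, alleles, amino-acid change under frame
offset 0, and differential BstNI/EcoRV/PciI digestion for pBD1/-4/-121 —
which forces the R/K context at position 65 to be AGA→AAA rather than
AGG→AAG, the only choice compatible with an overlapping EcoRV site), and
the 113-taxon prepropeptide panel reproduces the species counts
(29 pig, 36 human, 48 cattle) with motif-scaffold stand-in sequences.

## Problem sizes and determinism

Everything is driven by integer seeds through `numpy.random.Generator`;
identical configuration and seed give byte-identical files, and the
pipeline fans one seed into per-stage seeds by a fixed derivation. The
shipped demo configuration uses 2 contigs × 60 kb with 4 planted genes;
the recovery test suite uses a 1 Mbp genome with 10 planted loci on both
strands; oracle-equivalence suites run 10,000 random peptides and SNP
cases and 1,000 RFLP contexts; distance-recovery checks use 100
replicates of 1,000 sites. These sizes were chosen as the smallest at
which the properties of interest are sharp (exact recovery, ±0.03
distance recovery, binomial-SE frequency checks).

## Known limitations

- The guideless model builder handles the 2-exon case only; 3-exon loci
  need a guide cDNA (as in practice, where a transcript revealed the
  extra junction).
- The homology screen's rescue rule admits any short high-identity local
  match; on divergent panels, spurious micro-matches can carry `rescued`
  status. The pipeline prefers `pass` hits and only warns when a
  candidate's retention actually depended on a rescue.
- Bootstrap consensus at exactly the collapse threshold keeps a
  bipartition (≥, majority rule); conflicting bipartitions at exactly 50%
  are resolved by frequency-then-lexicographic order, which is
  deterministic but arbitrary.
- VCF output is minimal (4.2 header, per-gene local coordinates against
  the packaged exon-2 references); no genome build is packaged.
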
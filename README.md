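# defmine

Motif-constrained mining and comparative analysis of β-defensin gene
families, built as a reusable, fully tested Python library.

β-defensins are small cationic antimicrobial peptides defined by a
six-cysteine motif, **C-X₆-C-X₄-C-X₉-C-X₆-C-C**, encoded (almost always)
by two exons: exon 1 carries the signal/leader domain, exon 2 the mature
peptide with the cysteine scaffold. Because the family is both compact
and fast-evolving, genome-level surveys of it follow a characteristic
recipe that this package implements end to end:

1. **Discovery** — translate genomic contigs in all six frames, keep open
   reading frames containing the six-cysteine motif, confirm homology to
   a reference cDNA panel by local alignment (pass at identity > 70% and
   query coverage > 50%, strict; short hits with identity ≥ 80% are
   *rescued* rather than discarded), and build exon–intron models under
   the **GT-AG rule** — cDNA-guided when a guide is available, otherwise
   by junction enumeration that maximizes the motif-containing ORF.
2. **Phylogeny & naming** — global pairwise alignment (GONNET scores, gap
   open/extend 7/0.2), maximum-likelihood distances under the **JTT**
   empirical substitution model, **neighbor-joining** trees with
   majority-rule bootstrap consensus (branches under 50% support
   collapsed), and ortholog-based naming: a new gene takes the number of
   its nearest human reference, with clade membership as confirming
   evidence and a legacy table protecting historically established names.
3. **Synteny** — anchor-bounded clusters per chromosome, cross-species
   matching by gene number, and architecture events: conserved order,
   clusters split across chromosomes, duplications, order changes.
4. **Variants** — column-wise exon-2 SNP calling from diploid amplicon
   panels (IUPAC heterozygote codes supported), codon consequences under
   frame offset 0, folded minor allele frequencies, PCR-RFLP assay design
   by IUPAC-aware differential digestion, and in-silico PCR that
   distinguishes genomic from spliced templates by product size.

A first-class synthetic-data module generates genomes with planted
defensin loci (known coordinates, GT..AG introns, motif-free background),
divergent reference panels, and diploid populations with planted SNPs, so
every stage is tested against ground truth without any downloads. The
packaged fixture tables encode the study system's printed record: a
29-entry gene catalog (17 newly annotated, 10 previously reported, 2
partial ψ genes), an 8-row exon-2 SNP table, a 17-row primer table, and
the comparative cluster maps.

## Worked example

`examples/04_snps_and_rflp.py` rebuilds the SNP fixture population
(14 diploid animals, every tabulated variant planted) and runs the full
variant workflow:

```
pBD1     pos 171 A/G synonymous     aa -    MAF 0.107 (2n=28) RFLP: BstNI,ScrFI
pBD113   pos 114 A/G synonymous     aa -    MAF 0.071 (2n=28) RFLP: -
pBD114   pos 186 G/A synonymous     aa -    MAF 0.107 (2n=28) RFLP: -
pBD115   pos 144 A/T nonsynonymous  aa Q/H  MAF 0.071 (2n=28) RFLP: -
pBD115   pos 291 G/A synonymous     aa -    MAF 0.036 (2n=28) RFLP: -
pBD121   pos  96 G/A synonymous     aa -    MAF 0.107 (2n=28) RFLP: NlaIII,PciI
pBD133   pos 196 A/C nonsynonymous  aa K/Q  MAF 0.071 (2n=28) RFLP: MseI
pBD4     pos  65 G/A nonsynonymous  aa R/K  MAF 0.286 (2n=28) RFLP: EcoRV

8 coding SNPs in 7 genes; 3 nonsynonymous
```

Eight biallelic coding SNPs are called across seven genes; three change
an amino acid (R/K, Q/H, K/Q), the five synonymous ones all sit at third
codon positions, and the pBD1/pBD4/pBD121 polymorphisms are genotypable
by restriction digest (BstNI, EcoRV, PciI). MAF values here are the
realized sample frequencies of the 14-animal draw.

The other examples cover discovery on a simulated genome
(`01_simulate_and_discover.py`, which recovers every planted locus with
exact exon coordinates), distance/tree/naming (`02`), the pig–human
cluster comparison (`03`, including the split of the human chromosome 8
cluster across two pig chromosomes), and the one-seed end-to-end pipeline
(`05`). A thin CLI exposes the same stages:
`defmine simulate | discover | run | pcr | fixtures-summary`.

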
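# Methods

`polyals` re-implements, as reusable desk-scale computations, the
molecular-diagnostic workflow used to characterise ALS-inhibitor
resistance in polyploid *Echinochloa*: species barcoding with a
CAPS-rbcL marker, assignment of cloned *ALS* sequences to homoeologous
gene copies, target-site-resistance (TSR) codon calling, allele-specific
primer design with in-silico restriction validation, and ΔΔCt relative
expression of the gene copies. This note records the models, numerical
choices, and the scope of what the synthetic-data tests do and do not
demonstrate.

## Sequence primitives

Sequences are IUPAC nucleotide strings (U normalised to T); coordinates
are 1-based and inclusive throughout, and alignment gaps never consume
source coordinates.

**Distance.** Pairwise distance is the p-distance under pairwise
deletion: columns where either row shows a gap or N are excluded, and
ambiguity codes match iff their IUPAC sets intersect. No multiple-hit
correction is applied — every divergence in scope is below 5%, where
p-distance and corrected distances are indistinguishable for clustering
purposes. The all-pairs matrix is computed with a 4-bit base encoding
(vectorised, exactly equivalent to the scalar definition; the
equivalence is property-tested).

**UPGMA.** Classic average-linkage agglomeration: repeatedly merge the
cluster pair with minimal average linkage; the merged node sits at half
the merge distance, giving an ultrametric tree (verified to 1e-9).
Ties are broken by the lexicographically smallest pair of cluster keys,
where a cluster's key is the sorted tuple of its leaf labels — the
result is therefore independent of input order and platform. The
implementation is cross-checked against an explicit O(n³) brute-force
oracle and against SciPy's average-linkage heights.

**Alignment.** Pairwise alignment is global Needleman–Wunsch with match
+1, mismatch −1, gap −2 and free end gaps (delegated to Biopython's
`PairwiseAligner` configured with exactly those scores). Multiple
alignment is progressive over a UPGMA guide tree built from 6-mer
Jaccard distances, merging profiles through their consensus sequences.
The original analyses used commercial GUI aligners whose parameters are
not published; for the ≤3%-divergent homoeologs and ≤1%-error clone
libraries in scope, any reasonable global aligner returns the same
alignment, and the substitution-only fast path (equal-length inputs
pass through unaligned) is exact by construction.

**Consensus.** Majority rule per column with each residue voting for
every base in its IUPAC set; ties collapse to the ambiguity code of the
tied set, and gap-majority columns are dropped.

## CAPS barcoding

A CAPS marker is a primer pair plus a restriction enzyme whose site is
polymorphic between groups. The in-silico PCR model: the forward primer
binds the top strand, the reverse primer via its reverse complement;
at most `max_mismatch` mismatches per primer are tolerated but the
3'-terminal base must match exactly (Taq extension fails at 3'
mismatches); the unique shortest product is returned, with distinct
errors for no product and for ambiguous products. Defaults:
`max_mismatch=0` when applying a marker, 2 during discovery-time primer
placement, 1 for the deliberately mismatched allele-specific primers.

Restriction sites are IUPAC patterns with explicit cut offsets for both
strands (TasI `^AATT` 0/4; FokI `GGATG(9/13)` 14/18 from the site
start). Non-palindromic enzymes are scanned on both strands; for a
bottom-strand site, the bottom-offset cut is the one severing the top
strand. A site only counts when both strand cuts land inside the
molecule — a single-strand nick does not split a gel band. This
geometry is validated against Bio.Restriction as an independent oracle.
Fragment lengths are accounted on the top strand; sticky-end overhangs
are ignored. Band-pattern comparison ignores fragments under 30 bp,
which would run off the 2% agarose gel used for this assay.

The published CAPS numbers are mutually inconsistent: a 217-bp amplicon
cannot digest into 134+87=221 bp. The synthetic rbcL fixtures are
internally consistent and adopt the digest pair — the amplicon is
221 bp and the white haplotype cuts into exactly 134+87 — preserving
two of the three printed numbers. Resolving the discrepancy against the
real chloroplast sequence requires the GenBank records, which are not
bundled; the corresponding acceptance test states this explicitly.

## Homoeolog assignment

Each clone is a single sequenced molecule, hence one haplotype of one
gene copy. Copy number per species is recovered by clustering: align,
build the UPGMA tree, and cut at height `threshold/2`, so clusters are
groups with average divergence at most `threshold`. The default
threshold is 0.01 (1% p-distance), placed midway between the
sequencing/PCR error scale of the libraries (~0.002) and the
inter-homoeolog divergence of the templates (~0.02–0.03); it is exposed
in every API and in the pipeline config. Clustering honours the
hierarchical protocol — per plant, then per population, then per
species, then all together — implemented as successive re-clustering of
cluster consensuses with membership tracked back to the original
clones.

Full-length clone clusters are labelled by two signals: ALS1 is the
cluster containing clones of both species groups and (when present) the
known resistance mutations; ALS3 is the red-only cluster; ALS2 is the
remainder. Conflicting or absent signals raise an "anchor labeling
ambiguous" error listing the clusters rather than guessing. Partial
(5' 620-bp / 3' 1000-bp) libraries are assigned to anchor consensuses
trimmed to the same part — label transfer goes through consensus
sequences, not tree topology, because partial and full-length trees are
built from different coordinate ranges. Clones farther than the
threshold from every anchor, or exactly tied between two anchors, are
flagged unassigned rather than force-assigned (chimeric PCR clones
exist in real libraries).

## Mutation calling

Resistance positions are reported in standardized ALS codon numbering
(the herbicide-resistance convention of numbering against a reference
ALS protein). The shipped reference is a synthetic stand-in — a
deterministic 670-codon CDS carrying wild-type Ala122, Pro197 and
Trp574 — because the real reference coding sequence cannot be bundled;
any ALS-like reference can be substituted through the `ReferenceALS`
type without code changes. Queries are translated in the frame that
aligns best (stray stop codons from PCR error are treated as X rather
than disqualifying a frame), globally aligned to the reference protein,
and rejected below 50% identity.

At each watched codon the caller reports the observed codon, amino-acid
change, nucleotide edits, and a flag: wild-type, synonymous,
known-resistance (allele table: Ala122→{Val,Thr,Asn}, Pro197→{Ser,Leu},
Trp574→{Leu}), novel-nonsynonymous, or ambiguous (IUPAC ambiguity —
never called resistant). The Ala122Asn fixture uses GCT→AAT; note that
any Ala(GCN)→Asn(AAy) change necessarily edits codon bases 1–2 as
G→A plus C→A, and the caller reports those exact edits. Cross-tabulation
by copy flags any resistance call outside ALS1 with a warning instead of
suppressing it.

## Allele-specific primer design

Copy-diagnostic SNPs are columns where all target copies share one base
and all other copies share a different one. The design places the
forward primer's 3' terminus on one SNP and the reverse primer's 3'
terminus on a second, downstream SNP (on the bottom strand), following
ARMS-PCR practice; a deliberate mismatch — a base differing from every
template — is introduced at the third base from the forward 3' end, and
is checked never to coincide with the SNP nor to create a TasI/FokI
site inside the primer. Windows require within-class conservation only:
across-class differences inside a window are additional discriminating
positions that the class primer simply absorbs (the published reverse
primers differ at two positions for exactly this reason). Both classes
use the same windows, so amplicon lengths are equal by construction.
Primer lengths default to 20–25 nt; no melting-temperature or duplex
thermodynamics are modelled (the study handled dimers empirically via
dissociation curves).

Specificity is validated in silico by FokI digestion of every
design × template product: the report is "specific" iff amplification
is class-exact, the cut/uncut outcome is uniform within each class, and
the outcomes differ between classes — a combination of the two band
patterns never occurs.

On the synthetic templates the design reproduces the published primer
quartet: the reverse primers match the printed 25-mers exactly and the
forward primers extend the printed 22/23-mers by the same 3'-anchored
core. The printed forward primers differ in length by one base, so
their amplicons necessarily differ by 1 bp; the fixture puts the
ALS2-3 product at the printed 140 bp, making the ALS1 product 141 bp
with a FokI cut yielding the printed 105-bp band (plus a 36-bp
fragment, below gel visibility).

The published phrase "positions 590 (T/C) and 621 (C/A)" mixes units;
here both are interpreted as standardized codon coordinates containing
the discriminating nucleotides, and diagnostic SNPs are reported in
both nucleotide and codon coordinates so either reading is available.

## Relative expression (ΔΔCt)

Relative quantification follows the comparative-Ct method with an
assumed amplification efficiency of exactly 2 (a config hook allows
other values): ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt = ΔCt_sample − ΔCt_calibrator, RQ = 2^(−ΔΔCt). The defining
equation writes a single "reference" term; here the first parenthesis
uses the sample's own reference Ct and the second the calibrator's
(the standard Livak reading). The reference Ct is the mean over the
chosen reference genes of each gene's technical-replicate mean;
candidate reference genes are ranked by mean Ct (expression level) and
Ct standard deviation across samples (stability), combined by rank sum.

Aggregation order is fixed: technical replicates are averaged before
biological replicates; permuting replicate order changes nothing.
Technical triplicates spanning more than one cycle are flagged;
removal is only ever manual via an explicit exclusion list (the study
removed primer-dimer replicates the same way). Missing or
no-amplification Ct values are NA — excluded from means, never imputed.
Confidence intervals are two-sided 95% t-intervals on the biological
replicate mean (n=3 in the study design). RQ of the calibrator is
exactly 1 and all RQ values are invariant to a constant plate offset;
both properties are tested.

## Synthetic data generator

The generator emulates the study system, not any real genome. A fixed
synthetic 670-codon ALS CDS serves as both the numbering reference and
the ancestral template; homoeolog templates derive from it by seeded
random substitutions (stop codons excluded) at branch rates giving
~2–3% ALS1-vs-ALS2/3 and ~2% ALS2-vs-ALS3 divergence, with the shared
copies differing ~0.2% across species. The published primer binding
sequences are embedded verbatim at fixed coordinates (forward SNP in
codon 590 at CDS nt 1768, reverse SNP in codon 621 at nt 1862, FokI
site at nt 1837 in ALS1 only), so the printed primer strings work
unmodified on synthetic data; construction is re-verified against the
package's own CAPS/FokI invariants on every call. The rbcL haplotypes
(600 bp) embed the CAPS primers bracketing a 221-bp amplicon, a TasI
site at amplicon position 135 in the white haplotype only, and six
additional group-diagnostic substitutions.

Clone libraries sample copy-of-origin from configurable proportions
(defaults 55/30/15, the study's reported 3'-library mix), slice the
configured gene part (full / 5' 620 bp / 3' 1000 bp), inject the
population's resistance mutation into every ALS1-derived clone of
resistant populations (Ala122Asn for red, Trp574Leu for white), and
apply i.i.d. per-base substitution errors (default 0.002, the scale of
PCR + Sanger error in clone libraries; an indel option exists but
defaults to 0 because homoeolog assignment is SNP-driven). Truth labels
stay in clone metadata for recovery tests only — no analysis code reads
them.

The qPCR simulator draws 3 technical × 3 biological replicates per
population × treatment × target with Gaussian Ct noise (default sd
0.3 cycles). ALS targets sit at a base Ct of 28 (within the study's
observed 23–34 range); reference genes at ~22, truncated to the
printed per-gene ranges in the eight-gene screen. ALS1 is more
expressed by a configurable ΔCt (default 1.0 cycle) in every sample
except the untreated samples of the calibrator-eligible susceptible
populations, which define the baseline — so relative quantification
against an untreated susceptible calibrator recovers a 2-fold ALS1
excess, reproducing the direction (not the magnitude) of the study's
expression result.

**What passing tests show — and don't.** The synthetic libraries have
no chimeric clones, no indel error, no alignment uncertainty, and
divergences placed comfortably around the clustering threshold; recovery
of copy numbers, proportions and mutation positions under these
conditions validates the algorithms and their wiring, not their
robustness to the full messiness of real clone libraries. The qPCR
simulator is exactly the Livak model plus Gaussian noise, so fold-change
recovery validates arithmetic and aggregation order, not efficiency
mis-specification. Figure-level RQ magnitudes, Southern-blot band
patterns and field resistance phenotypes are wet-lab quantities outside
desk scale; only their qualitative directions are covered.

## Problem sizes and determinism

Default analysis sizes mirror the study: 42-sample barcode panels,
10–30 full-length clones, 138-clone 3' libraries, 7 populations × 2
treatments × 2 targets + 2 reference genes in qPCR. All randomness
flows through `numpy.random.default_rng` under explicit seeds; rerunning
any pipeline or generator with the same config and seed is
byte-identical, and the run manifest records the config hash and seed.
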
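# Methods

`iglocus` implements a desk-side workflow for characterizing immunoglobulin
(Ig) germline loci and heavy-chain CDR3 repertoires: structural annotation
of V/D/J/C gene segments in genomic sequence, IMGT-style functionality
classification, construction of a segmented germline reference, alignment
of junction amplicon reads with CDR3 extraction, and the standard
repertoire statistics. A first-class synthetic data generator provides
ground-truthed inputs for every stage.

## The annotation model

An Ig locus consists of variable (V), diversity (D, heavy chain only),
joining (J) and constant (C) gene segments. Somatic V(D)J recombination is
guided by recombination signal sequences (RSS): a conserved heptamer
(consensus `CACAGTG`) and nonamer (consensus `ACAAAAACC`) separated by a
poorly conserved spacer of 12 ± 1 or 23 ± 1 bp. The 12/23 geometry per
segment type and chain is fixed (`rss.CHAIN_RSS`): heavy-chain V carries a
23-spacer signal at its 3' end, D a 12 on both sides, J a 23 at its 5'
end; the kappa locus uses V-12 / J-23 and lambda V-23 / J-12.

**RSS scanning** (`scan_rss`) tests every placement of heptamer + spacer +
nonamer. Published annotations rarely state mismatch tolerances, so they
are explicit parameters: by default the heptamer must match ≥ 6/7 with its
first three bases (`CAC`, the functionally critical cleavage motif) exact,
and the nonamer ≥ 6/9 — the nonamer is the degenerate element, which is
also what sequence-logo analyses of real loci show. A relaxed setting
(`RssConfig.relaxed`) exists solely to *locate* candidates whose signal is
itself defective; the strict thresholds remain the bar for classification.

**V discovery** maps known germline seeds onto both strands (edlib infix
alignment iterated with masking, so every occurrence above the identity
threshold is found; identity = 1 − edits/len(seed)). The default
`min_identity` of 0.75 mirrors the family threshold; exon length must fall
in [240, 340] bp, a tolerance band around the ~290 bp V exons of bovid
loci. Each candidate keeps enough flanking context to be classified:
the upstream window is searched for a leader exon (ATG, a stop-free
stretch of 30–60 nt at a codon boundary, a GT donor, and an intron of
60–300 nt back to the AG acceptor), and the downstream window for the
chain's RSS.

**D discovery** is structural: a core of 5–40 bp flanked by 12-class
signals on both sides with G fraction ≥ 0.4 ("G-rich" is the only
published criterion; the threshold is exposed in config).

**J discovery** starts from the 5' signal. A candidate is kept when the
signal is strict, or when a relaxed signal is corroborated by an in-frame
W/F-G-x-G motif. This disjunction is deliberate: each single defect the
classifier must detect (degenerate heptamer, missing motif, missing donor
splice) still leaves the segment discoverable by the other signals. The
coding end is the first codon-boundary GT donor 30–70 nt downstream
(~50 bp J length, exclusive of the RSS); absent a donor, a default length
of 48 nt is used and the defect recorded.

**C discovery** chains seed-exon matches separated by < 800 bp into genes
and checks each intron for GT…AG boundaries.

Structural D/J search is masked away from regions claimed by seed-located
V/C genes (a signal-like motif inside a V exon or C intron is not a
candidate gene); the same mask construction is shared with the synthetic
generator's scrubber (below) so the two agree about what is searchable.

## Functionality classification

Classes follow the IMGT convention: **P** (pseudogene) for structural or
coding defects — in-frame stop, missing conserved C23/W41/C104 anchor,
missing initiation codon, missing donor or acceptor splice; **ORF** for an
intact reading frame whose only defects are regulatory — absent or
degenerate RSS, missing W/F-G-x-G motif, sub-threshold J heptamer;
**F** otherwise. A missing L89 is recorded as a warning, never a defect
(it is conserved in *most* V genes, not all). Every triggered rule is
recorded as a defect code, so P genes always carry at least one code and
F genes none. Ambiguous bases (N) in a coding region exclude a gene from
F (conservative on draft assemblies).

V numbering is approximated by BLOSUM62 local alignment to one built-in
template per chain whose residue index stands in for the standardized
position (anchors at 23/41/89/104); terminal residues clipped by the local
alignment are assigned positionally, so a substituted anchor is still
addressable. This is deliberately not the full IMGT unique-numbering
algorithm — the classification rules only consume the anchor positions and
the FR/CDR spans, and the template approach keeps the generator and the
classifier consistent by construction.

**Families** are single-linkage clusters of pairwise global nucleotide
identity at a 75% threshold (identity = matches / alignment columns; gaps
count as mismatches). Labels reuse the seed family name when a member
matches a seed above threshold, otherwise integers ordered by the
cluster's 5'-most member. **Naming** is positional 5'→3':
`<chain>V<family>-<locus ordinal>` for V; D/J genes are named within the
D-J-C cluster structure (`IgHJ1-4`, `IgHJ2-1`); loci with a single
cluster, or one gene per cluster, use flat ordinals (`IgκJ2`, `IgλJ2`) —
matching how such loci are named in practice; C genes get a flat ordinal,
omitted when the locus has a single C gene.

## Segmented reference and CDR3 convention

For every V gene whose conserved cysteine can be located, the reference
records FR1/CDR1/FR2/CDR2/FR3 nucleotide spans and the C104 codon offset;
for every J gene with a W/F-G-x-G motif, the FR4 span and the W/F codon
offset. **The CDR3 is anchor-inclusive**: from the V cysteine codon
through the J W/F codon, both included. This convention is used
identically by the reference builder, the read pipeline and the simulator;
under the exclusive convention all reported lengths would shift by 2 aa.
Serialization is a plain FASTA + TSV pair, deterministic (sorted) so
rebuilding a locus is byte-identical.

## Read pipeline

Reads are assigned the best V by scored local alignment (match +2,
mismatch −3, gap open −5, extend −2; minimum V score 50, J score 20 —
chosen so that zero-noise simulations align perfectly, and all exposed in
config). Both read orientations are considered; a fast edit-distance
prescreen (the 90 bp upstream of each V anchor) narrows candidates and
orientation before scored alignment, falling back to exhaustive scoring
when the prescreen fails. The J is aligned on the read suffix after the V.
Anchors are mapped through the alignment; a read whose alignment does not
cover both anchors is rejected (`ANCHOR_LOST`), as are reads without a
scoring V or J — rejections are data, not errors.

Junction bookkeeping: V/J deletions are read off the alignment end points
against the germline anchors. The D segment is the reference D sharing the
longest exact substring (≥ 7 nt, a conventional minimal confident core)
with the region between the V and J alignments; ties break by locus
order. Non-templated insertions are the unexplained remainder. Clonotypes
are grouped by exact (CDR3 nt, V call, J call) — MiXCR-like — and the
productivity filter removes junctions containing stops or whose length is
not a multiple of three (amino-acid reporting requires in-frame
junctions); removals are tallied per reason. Clonality statistics use
total counts; length and usage distributions use unique clones.

## Statistics

Inverse Simpson diversity (1/Σp²), analytic hypergeometric rarefaction
E[S(d)] = Σᵢ(1 − C(N−cᵢ,d)/C(N,d)) (deterministic, unlike Monte-Carlo
resampling; verified against exhaustive enumeration at N ≤ 12), top-k and
rare-clone proportions, the minimal clonotype count occupying a fraction q
of the repertoire (q = 0.31 by default, a parameter), pairwise overlap and
multi-sample shared clonotypes (default identity: exact CDR3 amino-acid
match, the common public-clone convention; switchable to nucleotide), CDR3
length histograms with an ultra-long report (> 50 aa, configurable), V/D/J
usage, and junction indel profiles. Printed percentages round half-up to
the precision conventional in sequencing summary tables (2 decimals for
alignment rate, 1 for unique/total).

## The synthetic generator and what it does (not) show

`generate_locus` plants structurally valid genes built from the package's
built-in synthetic templates into random intergenic sequence: V genes with
leader/intron/exon architecture and 3' RSS, G-rich D cores with dual
12-RSS, 48 nt J segments with motif and donor, multi-exon C genes. Defects
are planted surgically (one rule broken per gene) with a default load of
40% V pseudogenes cycling through every plantable code, 25%/50% J P/ORF
and a C pseudogene pair, echoing the mixed F/ORF/P composition of real
bovid loci. Family structure comes from two divergence tiers (~16%
between family bases, ~4% within), giving within-family identity ≈ 0.92
and between-family ≈ 0.70 around the 0.75 threshold.

Because the acceptance properties are *exact recovery*, the generator
guarantees its truth labels are well-defined: after planting, it scrubs
random flanks of any spurious signal that would make an alternative
annotation equally valid (leader-like ATG…GT patterns upstream of
init/donor-defect genes, stray RSS placements that form structural D/J
candidates), using the package's own discovery predicates so generator and
annotator agree exactly; a locus that cannot be disambiguated without
touching planted sequence is regenerated deterministically.

`simulate_repertoire` draws reads as V (by usage weight) → geometric(0.5)
3' trimming → Poisson(2) insertions per side of an optionally included,
lightly trimmed D → geometric 5' J trimming → point mutations (default 0)
→ clipping to a 200–300 bp amplicon window emulating a gel-purified PCR
product. Trimming never removes an anchor codon (biologically, such
junctions would not be recovered as productive clonotypes anyway).
Insertion bases are drawn so no germline alignment can extend into them —
verified with the same scored aligner the pipeline uses — because raw
trim/insertion counts are otherwise not identifiable from sequence; the
D/N split likewise follows the same longest-common-substring convention in
truth and pipeline. The `bovid_ultralong_spec` preset plants an extended
(126 nt) D-like core, stop-free in every frame, with an in-frame-only
junction model, producing the > 50 aa CDR3 regime for the ultra-long
reporting path.

What passing these tests does **not** show: the generator draws uniform
random intergenic sequence (no repeats, GC structure or assembly gaps),
plants one surgical defect per gene (real pseudogenes accumulate many),
models no somatic hypermutation, primer bias, sequencing-error profiles or
unalignable gDNA background (real amplicon alignment rates of ~13–27% are
dominated by such artifacts), and its junction model is a testing default,
not a fitted biological claim. Exact recovery on synthetic loci bounds
implementation correctness, not performance on a real 2.6 Gb assembly.

## Problem sizes and numerical choices

Default study conditions: loci of 30 V / 10 D / 8 J / 9 C genes in two
D-J-C clusters (~60 kb), repertoires of 10,000 reads — sizes at which
every acceptance property runs end to end in seconds to a couple of
minutes on one core. Determinism: every stochastic component takes a
single integer seed; the same seed yields byte-identical FASTA/GFF3/FASTQ.
Tie-breaks are fixed (best RSS by total matches then proximity; D
assignment by locus order; clonotype tables sorted by count then
junction). Degenerate inputs raise errors (empty seed sets, zero
clonotypes, depths exceeding repertoire size) rather than returning
silent defaults.

## Known limitations

- V numbering is template-based, not full IMGT unique numbering; exotic
  CDR1/CDR2 length variants may map anchors approximately.
- D/J discovery in regions not masked by V/C claims relies on RSS
  signal quality; heavily degenerate real signals below the relaxed
  thresholds are invisible.
- Isotype (C-gene) calling from reads is out of scope, as are paired-end
  merging, UMI handling and clonal-lineage phylogenetics.
- The Roman-numeral family labels some curated loci use for divergent
  clans are not reproduced; a single numbering scheme is applied.
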
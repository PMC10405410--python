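# Methods

This note documents the models, conventions and numerical choices behind
`charlink`, in the order the pipeline runs.

## The bridge-read model

A ChAR-seq library molecule is modeled as

```
cDNA (RNA side, transcript sense) + linker top strand + genomic DNA (forward strand)
```

with the 40 nt linker top strand `AANNNAAACCGGCGTCCAAGGATCTTTAATTAAGTCGCAG`.
The 13-mer tag `ACCGGCGTCCAAG` sits at offset 7, so the linker contributes a
7 nt arm 5′ of the tag and a 20 nt arm 3′ of it.  All arm lengths are
*derived* from `LinkerSpec` by locating the tag in the top strand — a custom
linker only needs consistent sequences.  Chemical modifications of the
physical oligo (5′ adenylation, 3′ spacer, phosphate, biotin-dT) do not
change base identity and are not modeled; the three N positions are
randomized per molecule.  Only the tag is computationally relevant: parsing
finds it (or its reverse complement, depending on which strand was
sequenced), excises the full linker, and reports the flanks.

Read emission follows the paired-end geometry in which the tag lies on
exactly one mate: mate 1 reads the molecule from the RNA end (forward
orientation) or from the DNA end of the opposite strand (reverse
orientation, tag appears reverse-complemented), and mate 2 reads the distal
fragment — the reverse complement of the DNA side when mate 1 is forward,
the RNA side when it is reverse.  Pair resolution mirrors this geometry:
the tagged mate's split defines both sides and the untagged mate extends
whichever side its orientation indicates, with a conservative consistency
check (prefix/suffix agreement) that falls back to the tagged mate alone.

**Fragment lengths.** RNA and DNA fragment lengths default to uniform
20–110 nt.  The upper bound keeps the tag and its 20 nt downstream arm
fully inside a 150 nt read in *both* orientations (a reverse-orientation
read reaches the tag only after the whole DNA fragment plus 33 nt of
linker), so at zero sequencing error every emitted pair is parseable and
round-trip recovery is lossless.  Real libraries are wider and lose a small
orientation-dependent fraction of junction reads; that loss mechanism is
deliberately excluded from the default so that parser losses are always
attributable to the length filter.

**Length filter.** Fragments of 17 bp or less are unusable; the filter
keeps pairs with both sides ≥ 18 bp (`--min-fragment-len`) and always drops
the whole pair, never one side.

## Mapping

The mapper is an exact-match substring index (18-mer seed, full-length
verification, both strands).  This implements the operative contract of
scored short-read alignment at desk scale — "keep a fragment only when it
has a single best placement" — in a form that can be verified against a
brute-force scan, which the test suite does.  Fragments with more than one
occurrence are discarded as multimappers, a hit on each strand counts as
two placements, N bases never match and fragments over 10% N are dropped
before mapping.  A `Mapper` protocol documents the adapter surface for
plugging in an external aligner; spliced alignment is out of scope (the
synthetic transcripts are unspliced).

RNA fragments are searched in the transcriptome (one unspliced transcript
per gene) and the genome.  When both placements name the same genomic
locus, transcriptome coordinates win; a genome-only hit is attributed to
the overlapping annotated gene if any, else it becomes `unassigned` and
feeds unkRNA detection; disagreeing placements drop the fragment as
ambiguous.  Contact coordinates are the 5′ end of each fragment on the
forward strand, 0-based half-open internally and 1-based inclusive in every
emitted table (stated in their headers).

## Contact statistics

- **CDI** = contacts on the most-contacted chromosome / total contacts.
  Defined only for genes with ≥ 1 contact; ties on the maximum are
  irrelevant.
- **Partition**: a contact is *cis*-proximal when it lies on the gene's
  chromosome strictly closer than 10 kb to the gene *span* (distance 0
  inside the span); exactly 10 kb falls in *cis*-distal.  Distance is
  measured from the span edges, not the midpoint, because nascent-like
  contacts align with the gene body.  Distance-from-locus histograms, in
  contrast, use the span midpoint, restricted to caps of 20/40/100/200/300
  kb.
- **Classification** is three-way and strict: cis-proximal when
  `f_cis_proximal > 0.5`, trans-acting when `f_trans > 0.5`, else
  unclassified (a gene at exactly 50% is unclassified).  A second scheme
  based on the total same-chromosome fraction (`classification_same_chrom`)
  is computed side by side, since "cis-acting" can reasonably be read
  either way; the default reported split uses the cis-proximal criterion.
  Partitioning is restricted to genes on the assembled macro-chromosomes
  (scaffolds are short and overestimate trans contacts).
- **unkRNA detection** tiles the genome with non-overlapping 10 kb windows
  (step configurable) and reports windows holding ≥ `min_contacts`
  (default 500) RNA-side positions of unassigned contacts while overlapping
  no annotated gene.  RNA-side coordinates define transcription; DNA-side
  coordinates would describe the contacted chromatin instead.
- **Concatenated coordinates** place the assembled chromosomes first (in
  numeric order), then all remaining entries alphabetically, for dot-plot
  axes; the mapping is invertible.

## Chromatin-mark association

Coverage is binned RPKM: each read is counted once, in the 50 bp bin
holding its 5′ start, and `RPKM = count / (bin_kb × total_reads / 10^6)`,
so the track integrates back to the read total.  (Counting every
overlapping read would double-count reads wider than a bin and break that
invariant.)  For each lncRNA with ≥ 100 contacts, the bin values at its
DNA-contact positions are compared with one background sample shared by all
lncRNAs tested against a track — 100,000 uniform random positions by
default, over the whole genome including scaffolds (flag to restrict) — by
a two-sided Mann–Whitney U test: exact null distribution when both samples
have ≤ 20 tie-free observations, tie-corrected normal approximation with
continuity correction otherwise.  BH adjustment runs within one track's
family; direction (higher/lower) is called from sample medians only when
q < α, with a mean fallback on exact median ties.  Sidedness is a package
choice: a two-sided test with post-hoc direction reports enrichment and
depletion symmetrically.

A desk-scale caveat the tests respect: contacts of a trans-acting lncRNA
avoid its own chromosome, so they are *not* uniform over the genome.  When
planted enrichment windows cover a non-trivial fraction of a small
synthetic genome, every lncRNA's contact sample drifts relative to the
uniform background.  The canonical association experiment therefore uses a
1.2 Mb genome with ±100 bp effect windows (≈4% of the genome), where the
planted 8-fold effect dominates and null lncRNAs stay at the nominal false
positive rate; on a real-sized genome the fraction is vanishing and the
caveat immaterial.

## Expression-target comparison

Targets are genes with ≥ 1 contact within TSS ± 5 kb, inclusive at both
ends (TSS = span start for `+` genes, span end for `−`; one TSS per gene
since the annotation is transcript-flat).  The default comparison unit
between two target sets is each gene's **median TPM across tissues**.
Pooling all gene × tissue values treats the ~75 correlated values of one
gene as independent observations and makes the rank-sum test strongly
anticonservative whenever genes differ in baseline expression; per-gene
medians keep the null calibrated, which the seed-sweep test verifies.
Pooled mode remains available (`mode="pooled"`) for comparability.
Comparisons refuse matrices with fewer than two tissue columns.

## The synthetic study generator

The generator's defaults are the package's reference study conditions:

- **Genome**: 6 assembled chromosomes plus alphabetically ordered
  unassembled scaffolds, uniform random sequence (so GATC occurs at the
  ~1/256 background rate and DpnII-anchored fragments exist everywhere).
  Chromosome sizes are chosen per experiment (50 kb–1 Mb) to keep runtimes
  in seconds-to-minutes; they rescale the genome, not the logic.
- **Annotation**: six RNA classes placed without overlap by sampling
  uniformly over remaining free gaps; class counts per experiment, e.g.
  3,176 lncRNAs for the detection-bookkeeping study.
- **Contact mixture** (liver profile): rRNA 70%, lncRNA 14%, mRNA 13%,
  snRNA 2%, msrpRNA 1%, snoRNA 0.04% over annotated classes (normalized to
  sum exactly to 1), plus a separate 10% intergenic mass emitted from ~30
  gene-free 2 kb loci so the unkRNA detector has signal.  Composition
  shares are reported over gene-assigned contacts, so the class
  percentages are recovered directly.
- **Planted lncRNA modes**: 87.5% cis-proximal / 12.5% trans-acting by
  default; a cis gene puts each contact within 10 kb of its span with
  p_cis = 0.9 (else uniform genome-wide), a trans gene on another
  chromosome with p_trans = 0.9 (else uniform on its own chromosome).
  mRNAs behave like nascent transcripts (half their contacts proximal);
  structural RNAs contact uniformly genome-wide.  DNA positions snap to
  the nearest GATC inside their intended region (downstream preferred,
  upstream fallback, untouched if the region has no site) so degenerate
  settings like p_cis = 1 stay exact.
- **Coverage and TPM**: ChIP-like reads start uniformly with intensity
  multiplied (divided) by the effect size in ±200 bp around
  enriched (depleted) sites; TPM draws are log-normal with per-gene
  baseline variation (σ_log = 1.0) and tissue noise (σ_log = 0.8) over 47
  embryonic + 28 adult tissue columns, with the "high" group's mean
  multiplied by the planted fold.

What the generator does **not** emulate: base-quality variation and PCR
duplicates, spliced transcripts, repetitive sequence (so multimapping is
rare rather than pervasive), copy-number structure of rDNA, and
tissue-specific expression architecture.  Passing tests therefore show
that the algorithms recover planted parameters under clean conditions;
they do not certify behavior on repeat-rich real genomes, where the
multimapper filter and the transcriptome/genome reconciliation carry much
more of the load.

## Determinism and problem sizes

Every emitter and every sampler takes an explicit seed and is
byte-deterministic for it; pipeline stages derive child seeds via
`SeedSequence` spawning.  The reference experiments used by the test suite
and the reproduction script run at: 1,188 lncRNAs × 200 contacts
(classification split), 3,176 annotated / 2,282 contacted lncRNAs
(detection), 10^6 read pairs end-to-end (composition recovery, a few
minutes on one CPU), and 200 replicates × 6 lncRNAs (association null
calibration).  These sizes were chosen as the smallest populations at
which the sampling error of each recovered quantity is well below its
acceptance tolerance.

## Known limitations

- Exact-match mapping has no mismatch tolerance, so the recovery rate
  decays with the sequencing error rate roughly as the probability that a
  fragment (and the tag) stays error-free; the parser/mapper tests assert
  monotonicity, not a specific error model.
- The untagged-mate merge assumes the distal mate belongs to the same
  unsheared molecule; chimeric artifacts would be absorbed by the
  conservative fallback rather than flagged.
- The 87.5/12.5 planted split and the >50% threshold interact: genes with
  propensities near 0.5 would classify unstably; at p = 0.9 with ≥ 200
  contacts the misclassification probability is negligible (< 10^-25 by a
  binomial tail bound), which is why planted-class recovery is asserted at
  ≥ 99%.
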
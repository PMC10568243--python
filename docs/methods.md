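# Methods

## Search model

A guide RNA is modeled as a DNA-alphabet protospacer (default 20 nt) plus
an IUPAC PAM pattern (default `NGG`) on a fixed side (3' for Cas9; 5'
supported for Cas12a-style nucleases). A candidate site is any genomic
window adjacent to a PAM-matching sequence whose alignment to the
protospacer fits three budgets: `max_mismatches` (default 4, the common
setting for SpCas9 off-target surveys), `max_dna_bulges` and
`max_rna_bulges` (default 0; bulges are rare and most published site lists
are mismatch-only). Both strands are searched by scanning the reverse
complement and mapping coordinates back to the forward genome, so a
minus-strand site at forward [s, e) corresponds to [L-e, L-s) on the
reverse-complemented sequence.

Conventions, chosen once and used everywhere:

* Coordinates are 0-based half-open and span the protospacer only; the PAM
  is stored separately. This gives direct BED round-trips and unambiguous
  interval arithmetic.
* PAM matching uses IUPAC expansion; PAM positions never count toward the
  mismatch budget, matching the convention of the established off-target
  search tools.
* Genome bases outside A/C/G/T (assembly gaps, ambiguity codes) match
  nothing — neither guide bases nor PAM codes. This is conservative: a run
  of N can never produce a reported site.
* Duplicate loci (reachable via different alignments) are collapsed keeping
  the minimum (total bulges, mismatches); output is sorted by
  (chrom, start).

With zero bulge budgets the scan is vectorised: per-position mismatch
counts are accumulated with numpy byte comparisons and the PAM gate is a
per-position membership mask, so a 10 kb genome scans in well under a
millisecond. With bulges enabled, windows of every feasible length
(guide ± bulge budgets) adjacent to each PAM occurrence are aligned by
dynamic programming.

### Gapped alignment

`align_gapped` globally aligns guide vs window. A DNA bulge is an extra
genome base (gap in the guide); an RNA bulge is an extra guide base (gap in
the genome). The DP table is indexed by (guide prefix, window prefix, DNA
bulges used, RNA bulges used) and stores minimal mismatches; among all
budget-respecting complete alignments the minimum under the lexicographic
cost (total bulges, then mismatches) is returned. Cost ties are broken
deterministically during traceback by preferring match/mismatch over a DNA
bulge over an RNA bulge, which yields one canonical alignment string
(codes: M match, X mismatch, D DNA bulge, R RNA bulge).

## Annotation model

Gene models (GFF3 or GTF) are reduced to gene-level segments: the exon
union over all transcripts defines "exonic"; introns are the gene span
minus that union (so exon ∪ intron exactly tiles the span); the CDS union
splits exonic sequence into CDS, 5'UTR (exonic bases 5' of the leftmost CDS
base, strand-aware) and 3'UTR. Genes without CDS have no UTRs. When a site
straddles segment boundaries the reported segment follows the precedence
CDS > 5'UTR/3'UTR > exon > intron — the most consequential class wins.

Promoters can be supplied as a BED track or derived from TSSs with a
−499..+100 window (the standard promoter-database convention; both bounds
configurable), mirrored on the minus strand and clipped at chromosome ends.

Interval intersection reimplements `bedtools intersect` defaults: half-open
overlap of at least `min_overlap` (default 1) shared bases, strand-blind —
Cas9 cuts both strands, so feature disruption does not depend on feature
orientation. The implementation uses a per-chromosome interval tree; its
contract is exact agreement with an all-pairs oracle, which the tests
enforce at 10^4 x 10^4 scale.

Gene-function tables are TSVs keyed by gene id (Ensembl-style; a trailing
".version" is stripped on both sides of every join). Lookups are total:
unknown genes return an all-empty record, so sparse tables never break the
pipeline. Regulator peaks, protein domains, miRNA genes and miRNA target
sites are recorded as evidence only. Peaks are reported independently of
promoters and additionally flagged when they co-occur with a promoter hit
at a site.

## Risk labeling

Candidates are collected per site: every protein-coding gene hit
contributes a coding-branch label (exonic + phenotype/cancer evidence →
high-coding; exonic otherwise → medium-coding; intronic → low-coding);
every other gene hit contributes a noncoding-branch label (exonic →
medium-noncoding, intronic → low-noncoding). Only when a site overlaps no
gene at all do promoter/enhancer hits contribute regulatory labels
(linked gene with evidence → medium-regulatory, else low-regulatory; a
regulatory element with no resolvable linked gene is treated as
low-regulatory — absence of evidence is not evidence of risk). The final
label is the maximum-severity candidate under the total order

    high-coding > medium-coding > medium-noncoding > medium-regulatory
    > low-coding > low-noncoding > low-regulatory > none.

Design choices that were genuinely open:

* The noncoding-branch labels and `none` complete the schema for sites in
  non-coding genes and intergenic sites; the exon/intron severity split in
  the noncoding branch parallels the coding branch.
* TF/co-TF and RBP status, protein domains, miRNA features and the
  mismatch count annotate a site but never change its tier (no rule ties
  them to severity; notably the 0-mismatch on-target is labeled by its
  region like any other site).
* Gating regulatory labels on "no gene overlap" makes coding precedence
  absolute: a site in a gene never gets a regulatory label. A consequence
  is a deliberate edge in monotonicity: adding disease evidence never
  lowers a site's severity, and removing an overlap never raises it —
  *except* that removing a site's only gene overlap can re-open the
  regulatory branch, whose medium tier outranks low-coding. The tests
  state monotonicity with exactly this carve-out.

## Synthetic worlds

The fixture generator emulates the full input surface with planted ground
truth. Defaults define the standard study conditions: a 20 kb single-
chromosome genome, one random 20-nt guide, `NGG` PAM, search budget 4
mismatches, and ten planted sites with mismatch histogram
{0:1, 2:1, 3:3, 4:5} — the 0-mismatch site is the on-target analog inside
the CDS of a disease-flagged coding gene — distributed over contexts that
exercise every risk label (coding exon/intron with and without evidence,
lncRNA exon/intron, disease and plain promoters/enhancers, one intergenic
site on the minus strand). Each planted protospacer carries exactly the
intended mismatches at random non-PAM positions; the random background is
rejection-sampled until an internal brute-force scan finds exactly the
planted sites and nothing else, so the manifest's site list is provably
complete for the budget. Gene structures are placed around each site to
force the intended segment; regulatory-context genes are placed clear of
their site so no gene overlap occurs. Function tables flag exactly the
intended genes (one phenotype gene, one cancer gene per world by default),
gamma-distributed TPM-like expression values are attached to coding genes,
and decoy miRNA features are placed where no site can reach them.

What the fixtures deliberately do not emulate: real human sequence
composition (GC structure, repeats), realistic gene density, overlapping
genes spanning multiple planted sites, or real database content and
identifier messiness. Passing the end-to-end tests therefore demonstrates
correctness of the mechanics (search, interval logic, joins, rules) on a
faithful miniature of the input formats — not calibration against real
GENCODE/OMIM/COSMIC snapshots, whose counts depend on database versions.

## Problem sizes and numerical notes

The test suite and the acceptance script run on deliberately small
instances — genomes of 1–20 kb, 10^4-interval intersection sets, 576-case
decision-table enumeration — sized so that exhaustive oracles (per-position
scans, all-gap-placement enumeration, all-pairs overlap) remain exact and
fast; the library itself has no such limits. Determinism: every stochastic
step flows from one integer seed through `numpy.random.default_rng`;
regenerating a world with the same seed is byte-identical, and the pipeline
itself is a pure function of its inputs. Degenerate inputs have defined
behavior: guides longer than every chromosome yield an empty site list (not
an error), empty BED files yield empty-but-valid reports, zero-length
intervals and inverted coordinates are rejected with line numbers, and
chromosome-name mismatches between layers produce an explicit warning
listing the unshared names rather than silently empty intersections.

## Known limitations

* No cleavage-efficiency or specificity scoring (CFD/MIT) — the output
  ranks sites by annotation-derived risk, not by predicted activity.
* Intergenic sites are not assigned to a nearest gene; only direct
  overlaps annotate.
* The bulge-enabled search is exact but per-PAM dynamic programming; it is
  meant for the small genomes and site lists this package targets, not for
  whole-genome scans with bulges.
* Risk tiers are ordinal labels, not probabilities; no cell-type-specific
  weighting of regulatory evidence is attempted.
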
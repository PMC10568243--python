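# casrisk

Off-target risk annotation for CRISPR-Cas9 guide design.

When a 20-nt guide RNA (gRNA) directs Cas9 to a genome, the nuclease can
also cleave at *off-target* sites — loci that resemble the protospacer
within a few mismatches (and possibly bulges) and carry a protospacer-
adjacent motif (PAM, canonically NGG). Whether such a cut matters depends on
what it disrupts: an exon of a disease gene is a very different event from
an intergenic cut. `casrisk` is a library + CLI that

1. **finds** candidate off-target sites by PAM-aware scanning of both
   genome strands under configurable mismatch/bulge budgets (or ingests a
   user-supplied BED of sites),
2. **annotates** each site against layered genomic tracks — gene models
   (with derived exon/intron/CDS/UTR segments), promoters, enhancers,
   transcription-regulator peaks, protein domains, miRNA genes and miRNA
   target sites — and joins gene-level functional evidence (genetic
   phenotypes, cancer roles, TF/co-TF class, RBP functions, tissue
   expression) through a shared gene identifier, and
3. **assigns a risk label** per site, tier x region:

   | label | rule |
   |---|---|
   | `high-coding` | exonic (CDS/UTR/exon) in a protein-coding gene with a known phenotype or cancer role |
   | `medium-coding` | exonic in a protein-coding gene without such evidence |
   | `low-coding` | intronic in a protein-coding gene |
   | `medium-noncoding` / `low-noncoding` | exonic / intronic in a non-coding gene (lncRNA, miRNA, pseudogene, TEC) |
   | `medium-regulatory` / `low-regulatory` | no gene overlap, but inside a promoter/enhancer linked to a gene with / without disease evidence |
   | `none` | intergenic |

   Sites overlapping several genes take the maximum-severity outcome; a
   site inside any gene never receives a regulatory label.

Coordinates are 0-based half-open (BED convention) throughout; site spans
cover the protospacer only, with the PAM held separately, and mismatches
are counted over the protospacer, never the PAM. Interval intersection
follows `bedtools intersect` semantics (strand-blind, >= 1 shared base).

Everything is testable offline: a synthetic-fixture generator builds small
genomes with planted on/off-target sites (exact mismatch counts, screened
backgrounds), gene models, regulatory tracks and function tables, plus a
ground-truth manifest that fully determines the expected pipeline output.

## Worked example

Generate a synthetic world and analyze its guide:

```sh
casrisk fixture --out world --seed 7
# -> fixture with 10 planted sites -> world
casrisk run --guide TGGTGTTAACCTTACTATAC --config world/config.yaml --out demo
# -> 10 sites -> demo
```

(The guide is recorded in `world/manifest.json`; seed 7 plants ten sites
with mismatch histogram {0:1, 2:1, 3:3, 4:5}.)

`demo/summary.csv` then holds one color-coded row per site; the first rows:

```
chrom,start,end,strand,...,mismatches,...,genes,biotypes,segments,...,risk_label,risk_rationale,color
chr1,901,921,+,...,0,...,gene1,protein_coding,CDS,...,high-coding,coding.exonic.disease,red
chr1,2921,2941,+,...,2,...,gene2,protein_coding,exon,...,medium-coding,coding.exonic,orange
chr1,4989,5009,+,...,3,...,gene3,protein_coding,intron,...,low-coding,coding.intronic,yellow
chr1,8807,8827,+,...,3,...,,,,...,medium-regulatory,regulatory.promoter.disease,orange
```

Reading: the 0-mismatch site at chr1:901-921 is the on-target analog — it
falls in the CDS of `gene1`, which carries a phenotype entry, so it is
`high-coding` (red). The site at chr1:8807-8827 overlaps no gene but sits
in the promoter of a disease-linked gene, hence `medium-regulatory`
(orange). `demo/` also contains `sites.bed`/`sites.tsv` (the raw search
output), `charts.json` (per-chromosome site counts, biotype x segment
distribution, risk-label distribution, expression of targeted coding
genes), and `tables/` with one TSV per annotation resource. `--format
xlsx|json` switches the export; `--html` adds a static report.

The same pipeline runs against real data by pointing `config.yaml` at a
genome FASTA, a GENCODE-style GFF3/GTF and BED/TSV annotation layers. For
example, the CCR5-targeting guide `CACCCGATCCACTGGGGAGC` searched against
GRCh38 with `--max-mismatches 4` reproduces the classic 118-site result
(1/0/1/15/101 sites at 0/1/2/3/4 mismatches); that genome is not shipped
here.

Input modes mirror typical usage: `casrisk search` (guide -> sites BED),
`casrisk annotate` (your own sites BED -> reports), `casrisk run` (both;
byte-identical to search piped into annotate).

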
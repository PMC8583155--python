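# srfam

Identification, classification and evolutionary analysis of plant **SR
(serine/arginine-rich) splicing-factor** gene families, with a seeded
synthetic-data generator so the whole pipeline is testable offline.

SR proteins are conserved pre-mRNA splicing factors. In plants they are
defined by one or two N-terminal RNA recognition motifs (RRMs) followed by
an **RS domain**: a region of at least 50 residues in which more than 20%
of positions lie in consecutive `RS` or `SR` dipeptides. `srfam`
implements, as a reusable library plus CLI:

- **RS-domain detection** — a residue is *covered* when it belongs to an
  adjacent `RS`/`SR` pair (overlaps allowed, so `RSR` is fully covered).
  With coverage mask *m*, all windows of length *L* = 50 whose covered
  fraction exceeds *c* = 0.20 qualify, and each maximal run of their union
  is reported as one domain.
- **Six-subfamily architecture classification** — rule-based calls from
  RRM count, the `SWQDLKD` heptamer in RRM2 (SR vs RS), CCHC zinc knuckles
  (one → RSZ, two → RS2Z) and an N-terminal RS/SP-dipeptide extension
  (SCL vs SC); proteins need ≥1 RRM hit (Pfam-style, E ≤ 1e-5) *and* ≥1 RS
  domain to enter the catalogue.
- **Physicochemistry** — average molecular weight, Kyte–Doolittle GRAVY,
  and isoelectric point by bisection of the Henderson–Hasselbalch net
  charge with the Bjellqvist (ExPASy-compatible) pKa set.
- **Gene structure** — exon/intron summaries per transcript and
  per-subfamily intron-count tables from GFF3.
- **Ks dating** — Nei–Gojobori (NG86) Ka/Ks with Jukes–Cantor correction,
  d = −(3/4)·ln(1 − 4p/3), and assignment of collinear pairs to the recent
  salicoid whole-genome duplication (Ks ≤ 1.0) or the core-eudicot γ
  triplication (1.2 ≤ Ks ≤ 2.8).
- **Expression rules** — 2^−ΔΔCt relative expression with two reference
  genes, differential calls (fold > 2 in either direction, Welch-t
  p < 0.01 on replicate ΔCt), the three-way RNA-seq DEG filter
  (TMM sum ≥ 5, |log2FC| > 1, FDR < 0.05), and stress-response summaries.

## Worked example

Generate a synthetic bundle (six planted proteins per subfamily plus five
decoys, codon pairs evolved at Ks 0.3 and 1.8, triplicate qPCR tables),
then run the pipeline:

```sh
srfam simulate --seed 11 --out-dir sim
srfam identify --proteome sim/proteome.fasta --hits sim/domain_hits.tsv \
               --gff3 sim/gene_models.gff3 --out-dir ident
srfam ks --pairs sim/alignment_pairs.tsv --out-dir ks
srfam qpcr --qpcr sim/qpcr.tsv --out-dir qpcr
srfam report --identify-dir ident --ks-dir ks --out-dir report
```

`report/report.tsv` then contains (abridged):

```
n_sr_proteins   36        # all 36 planted SR proteins recovered
n_SR            6         # …six per subfamily, none misclassified
n_RS2Z          6
n_rejected      5         # the five decoys, with reason codes
pi_min          5.23      # synthetic placeholders; real SR proteins are basic
introns_RS2Z_min 6        # RS2Z planted with a uniform six introns
introns_RS2Z_max 6
introns_SR_min  13        # SR genes planted intron-rich
ks_RECENT_WGD   10        # all pairs at true Ks 0.3
ks_GAMMA        4         # Ks 1.8 pairs: NG86 saturates for part of them
ks_AMBIGUOUS    6
```

and `qpcr/relative_expression.tsv` recovers the planted folds
(1.0 → 0.96 not significant; 4.0 → 3.87 and 0.25 → 0.26, both called
differential at p < 0.01):

```
gene  condition  fold    sd      pvalue      differential
G1    treatment  0.9593  0.0154  0.025357    False
G2    treatment  3.8716  0.4108  9.0609e-05  True
G3    treatment  0.2600  0.0238  0.00141202  True
```

The library surface mirrors the CLI: `find_rs_domains`,
`identify_sr_proteins`, `estimate_ka_ks`, `delta_delta_ct`, `deg_filter`,
and the generators in `srfam.synthetic`.

## Scope

Collinearity detection, multiple alignment, phylogeny reconstruction, read
mapping/quantification, and differential-expression model fitting are
consumed as inputs (MCScanX-style pair lists, aligned CDS pairs, TSV
expression tables), not reimplemented. See `docs/methods.md` for the model
details, parameter defaults, and known limitations.
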
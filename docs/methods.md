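# Methods

This note records the models and procedures `srfam` implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's numerical and
design choices.

## RS-domain detection

A residue is *covered* when it belongs to an adjacent `RS` or `SR`
dipeptide; overlaps are allowed (`RSR` is fully covered) and the unknown
residue `X` never participates. Given the coverage mask, every window of
length exactly `min_len` (default 50 residues) whose covered fraction
passes the content threshold (default 0.20) qualifies, and each maximal
run of the union of qualifying windows is reported as one domain with its
covered count.

Choices worth making explicit:

- **"over 20%" is strict** (`>`), with a `strict=False` switch for `>=`.
- **Fixed-length windows.** The union is taken over windows of length
  exactly `min_len`, not all longer windows. A long window can pass the
  threshold while containing no passing 50-window (its coverage may be
  spread too thin), so the two readings genuinely differ; the fixed-length
  reading keeps reported domains tight around dipeptide-dense regions
  instead of absorbing long dilute tails, and is what the brute-force
  oracle in the tests encodes.
- **Merged-region content is reported, not thresholded.** Every
  *generating window* passed the threshold; the union of several
  overlapping windows can have lower aggregate content. The threshold
  applies to windows only.
- Sequences shorter than `min_len` yield no domain; detection is O(n)
  via prefix sums and is checked exactly against an O(n²) enumeration
  oracle on randomized sequences.

## Architecture classification

A protein enters the SR catalogue iff it has ≥1 RRM domain hit surviving
the E-value cutoff (default 1e-5, the conventional hmmscan cutoff for
Pfam domain annotation) *and* ≥1 RS domain. Rejected candidates are
reported with reason codes `NO_RRM` / `NO_RS_DOMAIN`.

Same-kind hits are merged when they overlap by ≥50% of the shorter hit
(split envelopes from profile scans would otherwise double-count RRMs).
Subfamily rules fire in fixed order on the assembled architecture:

| rule | condition | call |
|------|-----------|------|
| R1 | 2 RRMs, `SWQDLKD` in RRM2 | SR |
| R2 | 2 RRMs, no signature | RS |
| R3 | 1 RRM, 2 zinc knuckles | RS2Z |
| R4 | 1 RRM, 1 zinc knuckle | RSZ |
| R5 | 1 RRM, no knuckle, N-terminal extension | SCL |
| R6 | 1 RRM, no knuckle, no extension | SC |

Anything else (≥3 RRMs, no RRM, no RS domain) is UNCLASSIFIED — a value,
not an error. `SWQDLKD` matching is exact by default (it is a signature
motif); a mismatch budget is configurable for divergent taxa.

Two descriptors are usually stated only qualitatively and are quantified
here with explicit, configurable defaults: an *SP-rich region* is any
window of ≥20 residues downstream of the last RS domain with ≥20% SP/PS
dipeptide coverage, and an *N-terminal extension* requires ≥2 overlap-free
RS/SR/SP/PS dipeptides before the first RRM. Both live in
`ClassifierConfig` and are logged in every run configuration, so a run is
reproducible even where the underlying literature is not quantitative.

## Physicochemistry

Average (not monoisotopic) residue masses with one water per chain;
Kyte–Doolittle hydropathy averaged over non-`X` residues; net charge by
Henderson–Hasselbalch with the Bjellqvist pKa set, including the
residue-specific terminal pKas, matching the ExPASy ProtParam tool the
field uses for these tables. The isoelectric point is found by bisection
of the (strictly decreasing) charge curve over pH ∈ [0, 14] to
|charge| < 1e-4; if the charge does not change sign on the interval the
boundary value is returned with a warning flag. `X` contributes zero
mass, is excluded from the GRAVY denominator, and has no ionizable group.
The implementation is cross-checked in the tests against Biopython's
ProtParam/IsoelectricPoint as an independent oracle.

## Gene structure

GFF3 1-based inclusive coordinates are converted once to 0-based
half-open; introns are the gaps between consecutive sorted exons. When a
gene has several transcripts the representative is the one with the
longest summed exon length (ties break on transcript id) — the usual
convention for Phytozome-style annotations when no primary transcript is
marked. Per-subfamily tables report min/max/mode intron counts and flag
subfamilies whose members all share one count.

## Ks estimation and event dating

NG86 counting: each codon position contributes the fraction of its nine
one-step neighbours that are synonymous (changes to stop codons count as
nonsynonymous); site totals are averaged over the two sequences. For a
codon pair differing at k positions, synonymous/nonsynonymous difference
counts are averaged over all k! orderings of the mutational pathway;
pathways through stop codons are excluded unless every pathway hits one.
Codon columns containing a gap, an ambiguity or a stop in either sequence
are dropped first; fewer than 10 comparable codons refuses the estimate
(`TOO_SHORT`). Proportions ps = sd/S, pn = nd/N are corrected with
Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 sets the `saturated`
flag. Estimates agree with Biopython's independent NG86 implementation to
~0.01 on simulated pairs (residual differences trace to stop-pathway
handling).

Duplication events are called from Ks alone: Ks ≤ 1.0 → recent WGD
(salicoid duplication), 1.2 ≤ Ks ≤ 2.8 → γ triplication, anything else
(including saturation) → ambiguous. The windows deliberately bracket the
Ks ranges reported for these events in *Populus*-scale analyses and are
fully configurable; category membership, not the point estimate, carries
the dating conclusion.

**Known limitation — saturation at γ-scale divergence.** At true Ks ≈ 1.8
a two-fold degenerate site can only toggle between its two synonymous
states, so the expected proportion of observed synonymous differences
exceeds the Jukes–Cantor domain and part of the simulated pairs saturate
or overshoot the γ window (≈half at 300 codons). This is inherent to
NG86 + JC at high divergence, not an implementation artefact; recovery at
Ks ≤ 0.6 is unbiased to well within 10%, and the recent-WGD category is
recovered exactly in simulation.

## Expression rules

2^−ΔΔCt with two reference genes: ΔCt subtracts the arithmetic mean of
the two reference genes' mean Cts in the same condition (equivalent to a
geometric mean of reference expression — the standard multi-reference
normalization); ΔΔCt subtracts the control condition; the replicate
spread is propagated as the SD of per-replicate 2^−ΔΔCt values. The
differential-response call requires fold > 2 or fold < 1/2 *and*
p < 0.01 from a two-sided unequal-variance (Welch) t-test on
per-replicate ΔCt with triplicates — the minimal defensible test for
three replicates, and swappable. The DEG filter keeps rows with
TMM expression sum ≥ 5, |log2FC| > 1 and FDR < 0.05; the upstream model
fitting that produces log2FC and FDR is consumed, not reimplemented.
Adding a constant to every Ct of a condition cancels in ΔCt (tested as an
invariant).

## Synthetic-data generator

The generator plants architectures from segment grammars: optional
N-terminal extension (SCL), 70–90-residue placeholder RRM segments (with
`SWQDLKD` embedded mid-RRM2 for SR), `C-x2-C-x4-H-x4-C` zinc-knuckle
placeholders, an RS stretch of 60 residues at ~50% dipeptide coverage,
and an SP-rich tail for RS2Z, plus RRM-only / RS-only / random decoys.
Filler alphabets contain no serine (and no arginine/proline inside
dipeptide-bearing segments), so coverage exists only where planted and
positives clear the 20% threshold with a wide margin. Matching domain-hit
rows are emitted by the generator itself; placeholder segments are *not*
required to be recognisable by real profile HMMs, so tests run without
any external profile database. Gene models draw 13–14 exons for SR, 7
for RS2Z (a uniform six introns) and 5–10 otherwise.

Codon pairs evolve a uniform-random stop-free ancestor by
Poisson(Ks·S) synonymous one-step substitutions placed uniformly over the
current synonymous opportunities (rejecting stops), optionally plus
Poisson(Ka·N) nonsynonymous ones. qPCR tables shift the target gene by
−log2(fold) cycles in the treatment condition around constant reference
baselines, with Gaussian Ct noise (default SD 0.1 cycles, triplicates).
Expression tables plant rows that pass all three DEG criteria and
background rows that fail exactly one.

What the generator does **not** emulate: realistic RRM/zinc-knuckle
sequence evolution, transition/transversion and codon-usage bias,
amplification-efficiency differences between qPCR targets, or read-level
RNA-seq noise. Passing recovery tests therefore demonstrates the
correctness of the detection/classification/estimation logic under clean,
clear-margin conditions — not robustness to the full noise structure of
real proteomes and expression assays.

## Problem sizes and numerics

Test and acceptance runs use 500 random sequences (length ≤ 300) for the
RS-domain oracle, a 41-protein proteome (6 per subfamily + 5 decoys) for
classifier recovery, 200 pairs of 300 codons at true Ks 0.3 for estimator
recovery (mean within ±0.03), and 50 seeds for qPCR fold recovery (mean
within 15%) — sizes at which every suite completes in seconds while the
Monte-Carlo standard errors are far inside the asserted tolerances.
Determinism: every generator takes one named seeded `numpy` generator; no
global random state. All internal coordinates are 0-based half-open with
a single conversion point at I/O; user-facing tables are 1-based
inclusive. Floating-point tie-breaks (window qualification, event
windows) use plain comparisons on IEEE doubles; thresholds are inclusive
exactly where the rule text says so (e.g. TMM sum ≥ 5 but log2FC strictly
> 1).
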
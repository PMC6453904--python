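# Methods

This note documents the models, conventions and numerical choices behind
`spermsnc`, in the order the pipeline runs.

## Coordinates and alphabets

All coordinates are 0-based, half-open internally; human-readable reports
may show 1-based closed intervals. Sequences are normalized to the DNA
alphabet at ingestion (U → T), and all matching happens in that alphabet,
because reference collections mix RNA and DNA conventions. Mature tRNA
references get a 3′ CCA appended when absent (flagged on the record),
since 3′-anchored fragments end in CCA in vivo.

## Read preprocessing

A 3′ adapter is trimmed when a prefix of the adapter, at least
`seed_len = 8` nt long, matches the read from some position through its 3′
end with at most one mismatch; the leftmost such position wins. Reads are
then filtered to `min_len = 15` – `max_len = 45` nt and mean Phred ≥ 20.
These defaults span the observed class length ranges (tsRNA 29–34 nt,
rsRNA 17–40 nt, miRNA 20–23 nt) with margin; they are explicit package
defaults, all configurable. Bookkeeping is conservative: input = surviving
+ length-filtered + quality-filtered, always.

## Annotation model

Matching is **exact and full-length** (mismatch budget 0; the
configuration hook exists but only 0 is implemented). Exactness makes the
naive-scan oracle, the read→feature identity and the naming scheme
unambiguous. Classes are tried in a hierarchy, default
miRNA → tRNA → rRNA → piRNA: short, uniquely defined classes first, so
miRNAs are not swallowed by long rRNA precursors. The index anchors each
read by its first 15-mer and verifies candidates by direct comparison, so
its hits are exactly the substring occurrences a brute-force scan finds.

Within the winning class: reads matching both a mature rRNA subunit and
the 45S precursor (which physically contains 18S/5.8S/28S) are assigned to
the mature subunit, so 45S does not absorb everything; remaining
multi-mapping is resolved toward the reference with the most read support
in the batch, ties broken by lexicographic reference id, and each read is
counted once. Only the sense strand is searched (small-RNA libraries are
stranded).

## Positional tsRNA typing

With anticodon interval [a0, a1) on a mature tRNA of length L, loop window
W = [a0 − loop_pad, a1 + loop_pad) and anchor tolerance t
(defaults loop_pad = 2, t = 3):

* start < t and end ∈ W → 5′-half; end before W → 5′-tRF
* end > L − t and start ∈ W → 3′-half; start after W → 3′-tRF
* both ends anchored → rejected as an intact tRNA, not a fragment
* anything else → i-tRF

The windows make the classifier total: every fragment interval receives
exactly one subtype (verified by exhaustive enumeration). The window
sizes are declared defaults, not recovered values — the verbal
region-based definitions of the five subtypes do not pin down boundary
behavior, so the package fixes it explicitly and configurably.

Feature identifiers are `<AminoAcidAnticodon>-<length>-<isoform>`
(e.g. `GlyGCC-30-1`), the isoform index assigned per (anticodon family,
length) group by descending cohort-mean abundance, ties by sequence, so
naming is injective and stable under sample reordering. The suffix is
always present internally, even for singletons, to keep identifiers
injective; displays may drop it. rsRNAs are named `<precursor>-<length>`
(`28S-58`), with an abundance-ranked suffix added only on collision, so
singleton names keep the familiar printed form. Whether isoform indices
should follow abundance or discovery order is genuinely open; abundance
was chosen because it is reproducible from the data alone.

## Quantification

Features are counted per distinct fragment (reference, start, end) for
tsRNA/rsRNA and per mature reference for miRNA/piRNA. RPM uses, by
default, the per-sample sum of feature counts (annotated sncRNA reads) as
denominator — this makes composition and RPM mutually consistent and the
column-sum identity (10^6) exact. tRNA-annotated reads rejected as intact
tRNAs sit in a separate bucket so read conservation still balances. The
expression floor keeps features with arithmetic mean RPM across all
retained samples (both groups pooled) strictly greater than 10.

Class composition is reported in two conventions: over annotated reads
(sums to 100%) and over all surviving reads including unannotatable ones
— the latter matches the usual "% of sncRNAs" phrasing when a fraction of
the library stays unannotated.

Cohort grouping: GQE rate ≥ 0.75 → H-GQE, ≤ 0.25 → L-GQE, otherwise
excluded; both boundaries inclusive.

## Differential expression

Two-sided Mann–Whitney rank-sum on RPM (rank tests are scale-invariant,
so no log transform is needed), exact when the smaller group has ≤ 8
samples and there are no ties, else normal approximation with continuity
and tie correction; completely tied data gives p = 1. The groups are
independent and unequal (23 vs 64), which is why the rank-sum form is the
default; a paired Wilcoxon signed-rank variant exists for equal-size
paired designs and errors otherwise. Benjamini–Hochberg is applied within
each class (tsRNA, rsRNA, miRNA tested separately, mirroring per-class
reporting). Significance defaults: BH FDR < 0.05 and |log2FC| ≥ 1 with a
1-RPM pseudocount — conventional declared defaults, all configurable.

## Panel evaluation

Panel features are transformed log2(RPM + 1), centered, unit-scaled
(RPM spans orders of magnitude). PCA is computed by SVD of the centered
matrix; variance explained covers all min(n − 1, p) components and sums
to 100%; component signs are fixed by making each loading vector's
largest-magnitude entry positive, so results are deterministic. The
classifier is a soft-margin linear SVM (C = 1 default; smallest
defensible model for ≤ 10-feature panels). The headline AUC uses
leave-one-out cross-validated decision scores; resubstitution is also
computed and labeled, since either convention is defensible and they can
differ materially. A single-class LOO training fold (possible only at
tiny n) falls back to the fold's constant prediction. The ROC is built by
an explicit threshold sweep with ties contributing diagonal segments; the
trapezoidal AUC then equals the Mann–Whitney U statistic scaled by
n1·n2 with half credit for ties (asserted in tests to 1e-12).

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes:
23 H-GQE (GQE rate uniform in [0.75, 1]) and 64 L-GQE samples (uniform in
[0.02, 0.25] — a strictly positive lower edge, since a 0% GQE couple is
rare), 100,000–300,000 reads per sample (per-sample depth is a desk-scale
stand-in; it is not a published quantity), class composition
tsRNA 0.56 / rsRNA 0.18 / miRNA 0.06 / piRNA 0.04 with the remaining 0.16
emitted as unannotatable random sequence to exercise that path.

**Count model.** Per sample, depth is split across classes by a
multinomial at the design composition. Within a class, each feature's
relative weight (log-normal, σ = 1, normalized within class) is perturbed
by a Gamma(1/φ, w·φ) draw — the mixing distribution of a negative
binomial — and counts are drawn multinomially from the perturbed weights.
Features therefore show gamma–Poisson-style overdispersion across samples
while per-sample class composition stays binomially tight around the
design values; a sum of independent negative binomials would not satisfy
both at once. The shared dispersion default is φ = 0.1, a typical bulk
small-RNA value at these depths, chosen so that the generator's
documented effect-size recovery contract (empirical spiked log2 ratios
within ±0.5 of design at the default cohort size) holds with margin.

**Fragments.** tsRNA fragment intervals are drawn per subtype
(5′-anchored start ∈ {0, 1, 2}; half vs tRF decided by whether the 3′ end
lands in the loop window) and verified against the classifier, so subtype
truth is well defined. Subtype mass: 0.68 5′-half / 0.14 5′-tRF / 0.07
3′-half / 0.05 3′-tRF / 0.06 i-tRF, putting > 75% on 5′-anchored
fragments. rsRNA precursor mass: 0.62 28S / 0.18 18S / 0.08 5.8S /
0.07 5S / 0.05 45S (45S fragments are drawn from spacer regions only, so
they are unique to the precursor). miRNA and piRNA reads are exact mature
sequences.

**Spikes.** The default design spikes 10 tsRNAs (5 down / 5 up in
L-GQE), 7 rsRNAs (6 down / 1 up) and 5 miRNAs (3 down / 2 up) at
|log2FC| = 2, applied as weight multipliers in the L-GQE group. Spikes are
taken from mid-abundance ranks so their combined weight share is small
and the within-class renormalization shifts realized fold changes by
≲ 0.12 log2 units. The truth table records class, subtype, interval,
spike flag, signed log2FC (L over H) and per-group expected RPM.

**Toy references** are desk-scale: 21 tRNAs (70–90 nt, anticodon spelled
into the sequence 32–38 nt from the 5′ end, 3′ CCA), rRNA precursors at
120 / 155 / 600 / 1500 nt with a 45S built as spacers plus the embedded
18S/5.8S/28S (so the mature-over-45S assignment rule is exercised), 40
miRNAs (20–23 nt), 30 piRNAs (26–31 nt). Real precursors are an order of
magnitude longer; length only affects index size, not the logic under
test.

**What the generator does not emulate:** sequencing errors and platform
quality profiles, isomiR variation, chemical modifications that block
reverse transcription, multi-mapping across near-identical tRNA copies,
batch effects, and piRNA differential expression. Passing tests therefore
demonstrate correctness of the pipeline's logic and calibration of its
statistics under the assumed generative structure — not robustness to
artifacts real libraries contain.

## Problem sizes and determinism

The test suite runs its end-to-end biomarker check on 10 seeds of the
23-vs-64 design at 20k–40k reads per sample, and its differential-power
and calibration checks on 20 seeds of the truth-count path (no read
emission); `scripts/acceptance.py` runs one full cohort at the default
100k–300k depth. One global seed drives references, design, per-sample
seeds and every stochastic draw; reruns are byte-identical (FASTQ gzip
mtime is pinned to zero).

## Known limitations

* Only exact matching is implemented; the mismatch-budget hook rejects
  non-zero values rather than silently approximating.
* The expression floor uses the pooled mean; per-group means would change
  which borderline features survive.
* With strong spiked effects and low dispersion the synthetic panels are
  nearly separable, so AUCs saturate at 1.0; the acceptance check is a
  lower bound (≥ 0.85), not a point reproduction of any published AUC.
* PCA variance-explained on a panel of co-regulated spiked features
  concentrates on PC1 by construction.
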
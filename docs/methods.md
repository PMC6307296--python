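# Methods

This note records the models implemented by `ccch-survey`, their parameter
defaults, the numerical conventions chosen where the literature leaves
latitude, and what the synthetic generators do and do not emulate.

## Motif model and scanner

A CCCH motif is `C-Xa-C-Xb-C-Xc-H` with spacer bounds `a ∈ [3,17]`,
`b ∈ [4,10]`, `c ∈ [1,5]` (all configurable via `ScanConfig`). Anchors must
be literal `C`/`H`; the ambiguity code `X` matches spacer positions only.
Two overlap policies:

- `report_all` — every `(start, a, b, c)` parse, in scan order.
- `non_overlapping` (default) — greedy left-to-right: at the leftmost
  anchoring cysteine admitting any parse, take the parse with minimal total
  spacer `a+b+c` (ties broken by smallest `a`, then `b`, then `c`), then
  resume scanning after the terminal histidine. Greedy-leftmost is the
  conventional census semantics; exhaustive parses remain available under
  `report_all` for sensitivity analysis.

Census types are keyed by the exact spacer triple. The common
`C-X7/8-C-X5-C-X3-H` display grouping is a presentation-level merge
(`MotifCensus.merged_fraction`), not a scanner feature.

**TZF / RR-TZF.** A TZF call requires a `(7,5,3)` or `(8,5,3)` hit followed
by a `(5,4,3)` hit starting 16–18 residues after the first hit's end. The
arginine-region signature `C-X5-H-X4-C-X3-H` (16 residues; anchors at
offsets 0, 6, 11, 15) is searched upstream of the first motif. The nuclear
export signal uses the consensus `Φ-X(2,3)-Φ-X(2,3)-Φ-X-Φ`,
`Φ ∈ {L,I,V,F,M}`, reported as leftmost non-overlapping shortest windows.

## Duplicate calling and classification

`DuplicationConfig` defaults: CDS coverage > 0.70 **and** protein identity
> 0.70 (both strict), tandem distance ≤ 100 kb, ≤ 10 intervening
non-homologues, clock rate `λ = 1.5e-8`/site/year.

Similarity uses global alignments (Biopython `PairwiseAligner`): BLOSUM62
with gap open −11 / extend −1 for proteins; match 2 / mismatch −3 / open −5
/ extend −2 for nucleotides. Coverage is the fraction of the shorter CDS
aligned to a residue (not a gap); identity is counted over protein columns
where both rows hold residues. Duplicate groups are connected components
(via `networkx`) of the pairwise duplicate relation, so a group may contain
pairs that individually fail the threshold. Tandem classification counts
genes strictly between the pair (by start coordinate) that are not members
of the duplicate group.

## Nei–Gojobori (1986) Ka/Ks

For each codon, the synonymous fraction of each position is the share of
the three possible point mutations that preserve the encoded amino acid;
mutations to stop codons count as nonsynonymous. Every position therefore
contributes exactly 1 site, giving `N + S = 3 × codons` identically. Site
counts are averaged over the two sequences. Codons containing a gap, `N`,
or a stop in either sequence are excluded pairwise.

Observed differences at multi-substitution codons are averaged over **all**
minimal mutational pathways with equal weight; a pathway step that creates
or leaves a stop codon is counted nonsynonymous (a stop encodes no
residue). This matches Biopython's NG86 implementation except on the rare
codon pairs whose pathways contain a stop→stop step, where Biopython counts
the step synonymous; the cross-check test restricts itself to codon pairs
that provably cannot touch a stop, making the dual-route comparison exact.

Proportions `pN = Nd/N`, `pS = Sd/S` are Jukes–Cantor corrected,
`d = −(3/4)·ln(1 − (4/3)p)`, undefined (`saturated`) at `p ≥ 3/4`.
`ω = Ka/Ks` is undefined when `Ks = 0`. Duplication age is
`T = Ks/(2λ) × 10⁻⁶` MYA — e.g. `Ks = 0.03 → 1.0` MYA, and the family's
dating window `Ks ∈ [0.0087, 0.5874]` maps to 0.29–19.58 MYA.

For unaligned inputs, `codon_align` threads each CDS through the global
protein alignment (three nucleotide gaps per residue gap), dropping a
trailing stop codon first.

## Phylogeny and subfamily assignment

p-distance is computed with pairwise complete deletion: columns with a gap
in either row are excluded; zero shared columns is an error. Neighbor
joining follows Saitou & Nei with the standard Q-criterion; ties select the
smallest `(i, j)` index pair, so trees are deterministic. Negative branch
length estimates are clamped to zero and the deficit transferred to the
sister branch, preserving path lengths where possible. On additive
matrices the implementation reproduces all leaf-to-leaf path lengths to
1e-9 (verified against random tree metrics and scikit-bio's `nj`).
Subfamily assignment gives each query the label of its nearest reference by
alignment p-distance, with queries beyond a ceiling (default 0.7) reported
`ungrouped`.

## Gene structure and chromosomal distribution

Exon statistics come from GFF3 gene models (longest isoform per gene, CDS
features falling back to exons), reported per gene and summarized (min,
max, mean). The chromosome census pools scaffolds and the `Ann`
pseudo-chromosome of unanchored genes as "unplaced" and reports genes/Mb
where chromosome lengths are known. Family-free intervals are maximal
gaps ≥ 10 Mb (configurable) between consecutive family genes, including
chromosome ends.

## Expression (2^−ΔΔCT)

Replicate Cq values are summarized by arithmetic mean before
`ΔCT = mean Cq(target) − mean Cq(reference)`; `ΔΔCT` contrasts a treated
stratum with the control stratum at the same time point; `fold = 2^−ΔΔCT`.
Dispersion is the standard deviation of per-replicate folds (replicates
paired by index). The reference gene is an explicit parameter. Adding a
constant to all Cq values of a stratum leaves folds unchanged. Response
classification: induced if max fold over the time course ≥ 2.0, suppressed
if min fold ≤ 0.5, else unchanged (thresholds configurable; induced takes
precedence). Peak time is the argmax of fold, ties resolved to the earliest
time. No amplification-efficiency correction is applied.

## Synthetic data

All test and acceptance inputs are generated, never shipped.

**Proteins with implanted motifs.** Backgrounds are drawn from the 18
non-anchor residues with `C`/`H` admitted at low weight (0.02) so spurious
anchors are rare; implants are separated by at least 19 background
residues, a gap large enough that no cross-implant CCCH parse can exist
under the default bounds. Generated sequences are rejection-resampled
(≤200 tries) until the scanner's truth exactly matches the implant plan.
The calibrated family instantiates a fixed plan of 103 proteins carrying
257 motifs in 15 exact types — `(7,5,3)`:105, `(8,5,3)`:106 (the 7/8 group
at 82.10%), `(5,4,3)`:17, plus twelve rare types — with copy numbers 1–6
and 17 TZF proteins that also receive the upstream RR signature and an NES
block. These sizes are this package's calibration choice for a
*Brassica*-scale family.

**Duplicate CDS pairs.** A stop-free random ancestor is mutated
independently along two lineages; synonymous and nonsynonymous event counts
are Poisson with means `Ks/2 × S` and `Ka/2 × N` over the ancestor's NG86
site counts, and each event is placed by rejection sampling uniform over
(codon, position, base) conditioned on its class — consistent with NG86's
fractional site weighting. Pairs are emitted aligned (no indels). Recovery:
median NG86 estimates over 200 pairs of 1,000 codons at `(Ks=0.2, ω=0.2)`
fall within 10% of target. Multiple-hit noise grows with divergence; at the
dating window's upper end (`Ks ≈ 0.59`) individual estimates scatter by a
few percent.

**Gene models, Cq tables, references.** Gene models place non-overlapping
genes on configurable chromosomes (optionally restricted to windows, used
to keep >10 Mb family-free stretches); the calibrated layout anchors 102 of
103 genes on A01–A10 (A03 = A09 = 16, A07 = 13, A10 = 11 on the shortest
chromosome) with exon counts 1–16 and single-exon TZF genes. Cq tables fix
the reference gene at Cq 18 and shift treated targets by `−log2(fold)` from
a baseline of 24, plus Gaussian noise. Reference panels for subfamily
assignment are grown per label and diverged by point substitution.

The generators emulate substitution processes and assay arithmetic only:
no indel evolution, no codon-usage or transition/transversion bias, no
rate heterogeneity, no amplification-efficiency variation, and no
homology between distinct background proteins.

## Limitations and open decisions

- NG86 (with JC correction) stands in for more elaborate Ka/Ks estimators;
  it is negatively biased at high divergence and ignores ts/tv bias.
- The 2-fold induction / 0.5-fold suppression cutoffs are conventions,
  surfaced as parameters.
- Duplicate *groups* are pure connected components; no synteny evidence is
  consulted, so tandem/segmental labels rest only on coordinates and the
  intervening-gene rule.
- The non-overlapping census counts motifs greedily from the left; a
  dynamic-programming maximum-packing census would be a reasonable
  alternative and can be approximated by post-processing `report_all`.
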
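# Methods

## Segmentation model

A GH7 cellobiohydrolase I candidate is modeled as the concatenation
catalytic domain → linker → CBM1.  Two anchors define the boundaries:

* **CBM1.**  The domain is anchored on its conserved `QCGG` core: with the
  rightmost `QCGG` starting at 0-based index *q*, the CBM1 span is
  `[q − 6, L)` for sequence length *L*.  The rightmost occurrence is used
  because CBM1 is C-terminal; the six-residue upstream offset reproduces the
  canonical Cel7A boundary (`TQSHYG|QCGG…`) and is configurable.  A missing
  motif, or one closer than six residues to the N-terminus, makes the CBM1
  absent (a recorded state, not an error).
* **Linker.**  The linker start cannot be read off the candidate alone; it is
  transferred from a reference through a pairwise global alignment.  Let *k*
  be the reference index of the last residue of the `FSNIK` anchor motif and
  *p* the candidate position aligned to *k* (if *k* is aligned to a gap, the
  nearest aligned reference position before it is used and noted).  The
  linker is `[p + 8, cbm1.start)`; the anchor's last residue and the
  eight-residue offset are the only unambiguous reading of "eighth residue
  downstream", and both are configuration parameters with these defaults.
  An empty interval yields an absent linker with a note.
* **Catalytic domain.**  `[0, linker.start)`.  For passing records the three
  spans partition the sequence exactly.

Filters apply in a fixed order, each recording its failure in the
annotation notes: (1) `QCGG` presence; (2) reference coverage — the percent
of reference positions aligned to candidate residues — must exceed 80,
mirroring the post-homology-search query-coverage filter; (3) occupancy of
CBH-specific loop windows on the reference must reach 0.8, removing
endoglucanases, whose loops are deleted.  Loop windows are user-supplied
reference spans: real-data use requires the published loop definitions,
which this package deliberately does not invent; the synthetic reference
model ships windows for testing only.

Alignment uses a global affine-gap aligner (BLOSUM62, gap open 10,
extension 1; a gap of length *ℓ* costs 10 + (ℓ−1)).  Among co-optimal
alignments the aligner's first traversal is taken, making coordinates
reproducible run to run.  Internal coordinates are 0-based half-open
everywhere; every emitted table converts to 1-based inclusive.

## Linker features and sequons

Composition counts exclude the unknown residue `X` from both numerator and
denominator (flagged per record).  Sequon scanning reports every
`N-X-[S/T]` occurrence, overlapping ones included; a sequon is
glycosylatable iff X ≠ P, since Asn-Pro-Ser/Thr is the canonical
non-functional sequon.  Dominant residues are ranked by total count pooled
over all linkers, ties broken alphabetically.

CBM1 conservation is summarized per column of an aligned set of CBM1
sequences: residue frequencies over non-gap symbols (gap fraction reported
separately, standard logo practice) and information content
IC = log₂20 − H(column) in bits, so an invariant column scores
log₂20 ≈ 4.32 and a uniform column 0.  An all-gap column has undefined IC
(NaN).  The pipeline profiles CBM1s directly when all extracted domains
have equal length (true for synthetic data by construction); unequal-length
sets require an external alignment first.

## Group statistics

Class comparisons report median and quartiles (linear interpolation,
"type-7" — the common default; the choice is stated because no convention
is universal) and mean ± sample SD, plus one-way ANOVA with Tukey-HSD
adjusted pairwise p-values (studentized range; `scipy.stats.tukey_hsd`).
Significance codes use strict inequalities: ns (p > 0.05), * (p < 0.05),
** (p < 0.01), *** (p < 0.001), **** (p < 0.0001); p = 0.05 exactly is ns.
Degenerate input in which every group is constant with equal means is
reported as F = 0, p = 1 (no evidence of difference) rather than 0/0.  A
two-group Mann-Whitney p accompanies the ANOVA as a rank-based robustness
companion; it is clearly secondary and never feeds the significance code.
No multiple-testing correction is applied across features.

## Tree congruence

The qualitative contrast "classes interleaved on the CBM1 tree, separated
on the catalytic-domain tree" is operationalized as a label-parsimony
score: the minimum number of class changes on the tree, computed by
unit-cost dynamic programming over node state costs (Sankoff).  On binary
trees this equals the classical Fitch count; on polytomies it remains exact
where the set-based Fitch rule is only heuristic, which is why the DP
formulation was chosen.  The count is invariant to rooting, so unrooted
inputs are scored as parsed.  For two classes the **mixing index**
normalizes steps *s* to (s − 1)/(min(n₁, n₂) − 1): 0 for monophyletic
classes, 1 when the minority class is maximally interleaved; it is this
package's own operationalization, labeled as such in reports, not a
published statistic.  Support values are read from internal node labels;
the support summary is the fraction of support-carrying nodes above a
threshold (default 50).

## Wet-lab conversions

* Glucan conversion (%) = 100 · (0.9·glucose + 0.95·cellobiose) / glucan
  load, the anhydro-correction compensating for water added on hydrolysis
  of glycosidic bonds.  Values above 100% warn (measurement noise) rather
  than error.
* Segal CrI (%) = 100 · (I₀₀₂ − I_am)/I₀₀₂, with I₀₀₂ the maximum intensity
  in the crystalline window (default 21.5–23.5° 2θ) and I_am the minimum in
  the amorphous window (default 17.5–19.0°), the conventional positions for
  cellulose Iβ with Cu Kα; both windows are configurable because published
  instruments differ.
* Band relative abundance (%) = 100 · I_t / I₀ per lane; 100 − value is the
  adsorption readout.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
every planted quantity recorded as ground truth.  Defaults are the study
conditions: 98 class-A (Sordariomycetes-like) and 96 class-B
(Eurotiomycetes-like) members; linker lengths Normal(28, 4) vs Normal(38, 4)
rounded and floored at 12; class compositions concentrated on the
T/S/P/A/N/G/Q/V/D alphabet with class A Pro/Ala/Asn-enriched and class B
Ser/Thr-enriched, chosen so the pooled dominant-residue order is
T > S > P > A > N > G and the between-class pattern is **** for length and
Ser/Thr/Pro counts; Gly is planted as a known null (equal expected
per-linker count in both classes, mean × frequency matched).  Sequons are
planted at a Poisson rate of 1.2 per linker with X = Pro probability
283/297 ≈ 0.953; accidental sequons arising from composition sampling are
removed (their Ser/Thr resampled from non-N/S/T letters) and planted X
residues are restricted to letters that cannot create overlapping motifs,
so the scanned sequons equal the planted ones exactly.  Both corrections
skip Gly so the null feature's count distribution stays an undistorted
Binomial mixture with matched means.  The catalytic region of each member
is the synthetic reference stub with 5% of positions substituted (anchors
protected); decoys are derived from clean members by destroying `QCGG`,
deleting the loop windows, or truncating 130 N-terminal residues (driving
reference coverage below 80%).  All randomness flows from one integer seed
through numpy's PCG64 generator; a fixed seed yields bit-identical output.

What the generator does **not** emulate: indels near the anchors, real
evolutionary covariation (sequences are not evolved along a tree), linker
O-glycosylation, CBM1 length variation, or alignment ambiguity.  Passing
tests therefore demonstrate the correctness of the rules and statistics on
unambiguous inputs, not robustness to the alignment noise of deep real-data
divergence.

Trees are generated with a mixing dial: 0 gives monophyletic classes, 1 a
random permutation of leaves on a random topology, intermediate values swap
`round(mixing · min(n₁, n₂)/2)` leaf pairs across the two class clades (the
count saturates at half-swapped, the maximal-interleaving point).
Saccharification tables are planted by inverting the conversion formula, so
the computed conversion reproduces the planted curve to rounding error.

## Verification strategy and problem sizes

Every rule is tested against an independent route: alignment scores against
an explicit three-state affine DP on random short pairs; sequon calls
against an overlap-aware regex; parsimony steps against exhaustive
enumeration of internal labelings on trees of ≤ 8 leaves, with rooting
invariance checked by rerooting at every edge; quartiles, F statistics and
the closed-form conversions against hand-derived values; Tukey p-values
against statsmodels.  Statistical behavior is checked by calibration: the
ANOVA type-I error over 1,000 null datasets at the study's group sizes must
sit in the binomial 99% band around 5%, and the planted significance
pattern must appear in ≥ 95% of 200 generated datasets.  That last joint
check is intrinsically tight: a perfectly null planted-equal feature is ns
with probability exactly 0.95, so the expected hit rate equals the
threshold and small-sample fluctuation matters; the generator keeps the
null undistorted precisely so the check sits at, not below, its nominal
level.  End-to-end determinism is verified by byte-comparing two complete
same-seed pipeline runs.  Problem sizes (500 sequences for boundary
recovery, ~250 with decoys for filter truth, 1,000 null simulations, 200
pattern seeds, 200 oracle trees) keep the full suite under a minute while
leaving estimator noise well below the decision margins.
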
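# Methods

This note records the models, algorithms and numerical conventions behind
`kaspfp`, the design decisions taken where the underlying methodology is
conventionally under-specified, and what the synthetic-data tests do and do
not demonstrate about real plates and panels.

## Genotype representation

Genotypes are unordered diploid allele pairs stored as alphabetically
sorted two-letter strings (`"AG"`, never `"GA"`); missing calls are `None`
(`NA` in CSV). All statistics treat a called genotype as two sampled
alleles. The numeric coding used by PCA, distances and the admixture model
is the counted-allele dosage g ∈ {0, 1, 2} with NaN for missing; the
counted allele defaults to the marker's minor allele (ties broken
alphabetically).

## Marker screening

The screening cascade applies four rounds in a fixed order and reports the
survivor count after each:

| round | predicate | default |
|---|---|---|
| 1 | minor allele frequency | MAF > 0.05 (strict) |
| 2 | missing rate | ≤ 0.20 (non-strict) |
| 3 | polymorphism information content | PIC > 0.30 (strict) |
| 4 | flanking isolation | no other input variant within 100 bp |

Strictness mirrors the usual phrasing of such protocols ("greater than" for
MAF and PIC, "removing loci with a missing rate > 0.2"). MAF and PIC are
computed from called genotypes only (denominator 2·n_called). Round 4 is
evaluated against the **full input variant list**, not the survivors of
rounds 1–3: a neighbouring variant disturbs allele-specific priming whether
or not it passed the statistical rounds. Distance is the absolute position
difference on the same chromosome, both flanks, bounds inclusive.

Rounds 1–3 are independent per-locus predicates, so their order only
affects the intermediate counts, never the survivor set; a property test
checks the cascade against the conjunction of all four predicates re-applied
by brute force.

Spacing selection is greedy per chromosome: loci in decreasing PIC (ties by
position), accepted when at least `min_gap_bp` from every locus already
accepted on that chromosome, until a per-chromosome quota is filled. The
quota and gap are exposed rather than defaulted, because published
protocols state "evenly distributed" without an operational rule.

Assay records are sequence-only: the allele-specific arm is the 20
reference bases ending at the SNP with the 3′ base set to the targeted
allele, the FAM/HEX tails are prepended verbatim, and the common reverse
primer is a fixed-placement 20-base reverse-complement window starting
30 bases downstream. Thermodynamic design (Tm/GC balancing, secondary
structure) is deliberately out of scope; in practice it is done by
dedicated primer software.

## Endpoint-fluorescence calling

A finished KASP plate is modelled as points in the (FAM, HEX) plane.
Processing steps:

1. **Baseline**: subtract the per-channel mean of the no-template-control
   (NTC) wells; clip negatives at zero. At least one NTC is required (two
   per plate is standard practice).
2. **No-call gate**: wells whose signal magnitude √(FAM² + HEX²) does not
   exceed the NTC magnitude mean plus `min_magnitude_sds` (default 6) NTC
   magnitude standard deviations are no-calls. The gate is monotone: a
   stricter threshold can only add no-calls.
3. **Clustering**: remaining wells are clustered on the angle
   θ = atan2(HEX, FAM) by deterministic 1-D Lloyd iterations initialised at
   the canonical genotype angles (0°, 45°, 90°; for k = 2, the best of the
   three canonical pairs by inertia). k ∈ {1, 2, 3} is chosen by mean
   silhouette, computed classically except that a singleton cluster scores
   1 rather than being rejected (tiny plates legitimately produce singleton
   clusters); k = 1 carries a fixed pseudo-score of 0.6, so a multi-cluster
   split must beat that floor. Angle space was chosen over 2-D intensity
   clustering because it is invariant to the well-to-well amplitude
   variation that dominates plate noise.
4. **Labelling**: cluster mean angles are assigned to the canonical angles
   by a minimum-cost injective (Hungarian) assignment; the lowest angle is
   the FAM-allele homozygote, the highest the HEX-allele homozygote, the
   middle (when present) the heterozygote. Swapping the FAM and HEX
   channels therefore swaps the homozygote labels and fixes heterozygotes.

**Triage.** An assay is `indistinct_or_failed` when the no-call fraction
exceeds 0.2, when adjacent clusters are separated by less than 15° of
*clear* angle, or when a single called cluster is too diffuse (angular sd
above the same threshold); it is `monomorphic` when exactly one genotype
class is called cleanly; otherwise `core`. The separation statistic is
edge-to-edge — centre gap minus two angular standard deviations per flank —
not the raw centre gap: k-means centres stay near the canonical angles
however much clusters overlap, so a centre-gap rule cannot detect smeared
plates, whereas the edge gap goes negative exactly when the clouds merge.
The raw centre gap is retained in the quality block as `min_center_gap_deg`.

**Replicate concordance** is reported over samples fully called in every
replicate: the fraction whose genotypes are identical across all
replicates; error rate is its complement. Two documented alternatives are
flagged options: counting any-no-call samples as discordant, and a
pairwise-replicate denominator.

## Diversity statistics

For allele frequencies p₁…pₖ estimated from called genotypes:

* gene diversity (expected heterozygosity) D = 1 − Σ pᵢ², reported without
  the n/(n−1) small-sample correction (the convention of the standard
  marker-table software; the corrected variant is available via
  `unbiased=True`);
* PIC = 1 − Σ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ², the biallelic special case being
  2pq − 2p²q² with maximum 0.375 at p = 0.5;
* observed heterozygosity = heterozygous calls / called samples;
* missing rate = missing / total samples, printed as a percentage.

Internal values keep full precision; rounding (half-up, 3 decimals for
fractions and 2 for percentages) happens only in the report layer, matching
how such tables are printed. One caveat worth knowing when validating
against published tables: statistics recomputed from a *printed* (3-dp)
MAF can differ from the printed statistic by one unit in the third decimal,
because |dD/dp| ≤ 2 lets the half-ulp input quantisation cross a rounding
boundary. The tests therefore check printed tables for interval
consistency (the printed value must be attainable from some frequency that
rounds to the printed MAF) rather than for naive re-rounding equality.

## Population structure

**Distance.** The default between-accession distance is the allele-sharing
p-distance over pairwise-complete loci: d = 1 − (shared alleles)/(2·L),
where a locus contributes the multiset intersection size of the two allele
pairs (equivalently 2 − |gᵢ − gⱼ| in dosage). It is a semimetric in [0, 1],
zero exactly on identical profiles. Nei's (1972) standard distance between
group frequency vectors is provided separately for between-population use.

**Neighbor joining** follows Saitou & Nei with the standard Q-criterion,
deterministic tie-breaking by the label-sorted pair, an unrooted
trifurcation at the end, and negative branch-length estimates clamped to
zero with a count of clamped branches (the convention of mainstream tree
viewers). NJ is exact on additive matrices, which the tests exploit:
random trees are generated, their path-length matrices fed back, and the
reconstruction must match to numerical precision; topology is also
cross-checked against an independent NJ implementation on perturbed
matrices. Bootstrap support resamples loci with replacement, rebuilds the
tree, and scores each internal bipartition of the point tree by its
replicate frequency.

**PCA** codes genotypes as minor-allele dosage, mean-imputes missing cells
per marker, centres columns and eigendecomposes the covariance (full SVD,
deterministic). Components are reported with their variance fractions.

**Admixture.** The fitted model is the standard admixture likelihood:
accession i has ancestry proportions Qᵢ on the K-simplex, population k has
allele frequency Pₖₗ, and the dosage is Binomial(2, Σₖ QᵢₖPₖₗ). The
published workflow this package mirrors used a Gibbs-sampling
implementation (long burn-in MCMC, ten replicate runs per K);
re-implementing that sampler is out of scope here. Instead the same
likelihood is maximised by the classical multiplicative EM updates
(FRAPPE-style), which ascend monotonically, from seeded Dirichlet/uniform
initialisations with five restarts, keeping the best final likelihood.
Frequencies are clipped to [10⁻⁶, 1 − 10⁻⁶]; convergence is a log-likelihood
change below `tol` (default 10⁻⁶). Ancestry components are identified only
up to permutation; `AdmixtureResults.aligned_Q` aligns to a reference by a
Hungarian assignment on mean absolute column differences. EM point
estimates are not posterior samples: they give desk-scale structure
estimates and feed the ΔK machinery, but will not numerically replicate
MCMC outputs.

**Evanno ΔK** is computed per K from a table of replicate log-likelihoods:
L′(K) = L(K) − L(K−1), |L″(K)| = |L′(K+1) − L′(K)|, ΔK = |L″(K)|/s(K) with
s(K) the replicate sample sd (n−1 denominator) — the per-K quantity plotted
by the standard Evanno tools (the original paper phrases the numerator as a
mean over replicates; for a rectangular run table the two agree). ΔK is
undefined at the boundary K values and wherever s(K) = 0, which is flagged
rather than raised. The calculator accepts any externally produced run
table, so MCMC runs can be analysed the same way.

## Fingerprinting

Profiles are stored verbatim, missing calls included and never imputed.
Two semantics coexist and are kept deliberately distinct:

* **profile distinctness** (used by `discrimination_count`): missing
  compares equal to missing and unequal to every call;
* **pair separation** (used by duplicate detection, greedy selection and
  matching): a pair is separated by a marker only where *both* are called
  and differ — a missing call is evidence of nothing.

Separation implies distinctness, so a greedy subset that separates all
pairs always yields n distinct profiles; the converse can fail on missing
data, which is why the greedy selector reports terminally unseparated pairs
instead of claiming completeness from distinctness.

Greedy selection adds, at each step, the marker separating the most
not-yet-separated pairs (ties: higher PIC, then database order) — directly
optimising the identification-efficiency quantity plotted in such studies —
and emits the per-step curve (distinct profiles, fraction of pairs
separated), both non-decreasing. The greedy subset is small but not
certified minimal; tests compare it against exhaustive subset search on
small databases, asserting only completeness and that greedy size ≥ the
true minimum.

Query matching counts mismatches over mutually called loci; a verdict of
"matched" requires zero mismatches with at least `min_overlap` loci
compared (default 20 of a 31-marker panel — the threshold is a package
choice, exposed as a flag, since matching protocols rarely state one).
Below the overlap for every entry the verdict is "insufficient data";
otherwise "no match", with candidates ranked by (mismatches, more loci
compared first).

The exported fingerprint matrix uses the conventional colour code:
homozygous AA yellow, GG orange, CC blue, TT purple; any heterozygote
green; missing grey.

## Synthetic data

The generator emulates the study design this package targets: ~105 diploid
accessions typed at ~31 biallelic markers in K = 3 admixed subpopulations,
with low MCAR missingness (defaults: missing rate 0.02 per cell, matching
observed per-marker missing rates of 0–5%; F = 0.15; Dirichlet α = 0.2 for
moderately admixed ancestry; ancestral minor-allele frequencies uniform on
[0.1, 0.5]).

* Subpopulation allele frequencies follow the **Balding–Nichols** model:
  Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral p, collapsing to p at
  F = 0. This model was chosen because it is the standard one-parameter
  (FST) differentiation model and permits parameter-recovery testing.
* Ancestry rows are Dirichlet(α·1_K); genotypes are Binomial(2, Σₖ QᵢₖPₖₗ);
  missingness is completely at random per cell (the low observed rates in
  real panels suggest no structured mechanism worth modelling).
* Accessions are treated as unrelated admixed individuals: real germplasm
  collections contain clones, cultivars and sibs, which is precisely what
  the fingerprinting layer detects, but no pedigree is simulated.
* Plates place each genotype class at a canonical angle (0°/45°/90°) at a
  common amplitude with isotropic Gaussian noise; NTCs and dropout wells
  sit at the origin with the same noise; negative intensities are clipped
  at zero as detectors do not report them. There are no linkage, selection,
  plate-edge or amplitude-gradient effects.

Every stochastic operation takes an explicit integer seed and is
bit-for-bit reproducible for a fixed seed and library version.

Because the generator realises exactly the assumptions of the downstream
models, passing tests demonstrate correctness of the algorithms and
internal consistency of the pipeline — not robustness to the ways real
data violate those assumptions (linked loci, related accessions,
non-random missingness, asymmetric fluorescence gain).

## Problem sizes used in the automated checks

The test suite runs at deliberately modest scales chosen to exercise each
property well away from its decision boundaries: 96-well plates with three
replicate seeds for caller recovery (≥95%) and concordance (≥97%); an EM
recovery run at n = 150, L = 100, K = 3, F = 0.25, α = 0.1 (mean absolute
Q error < 0.15 after alignment); 50 random additive matrices with up to 10
taxa for NJ exactness; exhaustive subset search up to 8 accessions × 6
markers for the greedy oracle; and 100 simulated 60-locus panels for the
filter-cascade brute-force re-check.

## Known limitations

* The reverse-primer window is a placeholder; real assays need
  thermodynamic design.
* The EM admixture fitter finds local maxima; five restarts suffice at
  desk scale but hard datasets may need more (`n_restarts`).
* Bootstrap support on panels with heavy missingness can drop replicates
  whose resampled loci leave some pair with no comparable locus; such
  replicates count as non-supporting.
* ΔK cannot assess K = 1 (its own well-known limitation), and with EM
  restarts replicate spread s(K) reflects optimisation noise rather than
  MCMC posterior spread.
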
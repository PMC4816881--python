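# Methods

This note documents the models, parameter choices and numerical decisions in
`sialoquant`, in the spirit of a statistical-methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Quantitative model of the experiment

One 4-plex isobaric run measures, for every identified spectrum, four
reporter intensities — two channels per condition (mock vs ST3GAL4). On the
log₂ scale the package models a measured intensity as

```
y = protein abundance + peptide offset + run offset + channel shift
    + condition effect (glycopeptides only, case channels only) + ε
```

with ε ~ N(0, σ²). This additive decomposition is the minimal model in which
each normalization step removes exactly one term:

* per-channel **median centering** removes the channel shift (unequal mixing,
  labeling efficiency) because the bulk of features is unchanged between
  conditions, so the channel median tracks the shift;
* **rollup** removes peptide offsets: every contributing row is centered on
  its own cross-sample mean, the centered rows are averaged per sample, and
  the grand mean (mean of the row means) is restored. Single-row groups pass
  through unchanged. Modified peptides allow one-hit wonders; protein rollup
  requires ≥ 2 unique peptides (a peptide is "unique" when its plain
  sequence maps to exactly one accession) and reports dropped accessions;
* per-run **mean centering** of each feature removes the run offset, making
  the three replicate runs commensurable;
* subtracting the rolled-up **protein profile** from each glycopeptide
  profile cancels the protein-abundance component, leaving the sialylation
  change proper.

Missing values are skipped, never imputed; a glycosite needs ≥ 2 non-missing
values per condition to be tested, and untested features are reported, not
silently dropped.

## Differential testing

**Moderated t.** Per feature: difference of condition means, pooled
within-condition variance s² on d degrees of freedom. The variance prior
(d₀, s₀²) is fitted by method of moments on z = log s², using the exact
moments of log-χ²: E z involves ψ(d/2), Var z involves ψ′(d/2); d₀ solves a
trigamma equation (Newton inversion), s₀² follows from the mean equation.
When the observed spread of z is no larger than expected under homogeneous
variances, the prior is degenerate (d₀ = ∞) and every variance shrinks to
mean(s²). Then s̃² = (d₀s₀² + d s²)/(d₀ + d) and t = Δ/(s̃√(1/n₁+1/n₂)) with
d₀ + d degrees of freedom. With d₀ = 0 this is exactly the ordinary pooled
t; one test cross-checks the whole fit against the Bioconductor
implementation of the same model on identical input.

**Rank product.** Per replicate run, the case-minus-control mean log₂ ratio
is ranked across features (rank 1 = most up-regulated); RP is the geometric
mean of a feature's ranks, computed separately for up and down (down uses
the reflected ranks m+1−r of the same orderings). The permutation null
shuffles feature labels independently within each replicate; up and down
p-values use the same draws, with add-one smoothing
p = (1+#{RP\* ≤ RP})/(B+1) so p ∈ (0,1]. An `exhaustive` mode enumerates all
(m!)ᵏ arrangements for tiny instances and is tested against independent
brute-force enumeration. Ties get average ranks.

**Combination.** The combination operator behind "combined moderated-t and
rank-product testing" is genuinely open, so it is a pluggable strategy with
two implementations:

* **union** (pipeline default): p = min(1, 2·min(p_mod, p_rp)), both inputs
  two-sided. This is a Bonferroni bound on the union, a valid p-value under
  arbitrary dependence; a feature counts if *either* test finds it. Power is
  then driven by the moderated t, with the rank product contributing
  robustness when variances misbehave.
* **intersection**: per side, p = max(one-sided p_mod, one-sided p_rp),
  doubled. This demands support from *both* tests. It is provably low-powered
  in a multi-effect world: a feature whose within-replicate rank is r cannot
  get a rank-product p below ≈ (r/m)ᵏ·polylog, so its Storey q scales like
  (r/m)²·polylog — independent of m — and only the extreme top of the
  ranking can ever pass an FDR threshold, no matter the effect size. On the
  package's default synthetic world the intersection rule recovers ~20% of
  true effects where the union rule recovers ~90% at the same realized FDR,
  which is why union is the default. The standalone `combine_tests`
  operation keeps the conservative max rule as its default contract.

The reported direction is the sign of the mean log ratio; the reported
rank-product p is the one-sided p on that side.

**Storey q-values.** π̂₀(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05…0.90 (step
0.05), smoothed by a cubic polynomial fit evaluated at λ = 0.90 and clipped
to (1/m, 1]; for m < 100 the noisy fit is replaced by the fixed λ = 0.5
estimate. q is the running minimum of π₀·m·p₍ⱼ₎/j from the largest p down,
which resolves ties at the deepest rank (the standard convention; for m
identical p-values q = π₀·p).

**Biological gates.** Significant sites (q ≤ 0.05) are kept only if the
deamidated Asn sits in a consensus sequon — N-X-[S/T/C] with X ≠ P — on a
membrane-annotated protein. N-G-[S/T/C] sites pass with a `potential_NG`
caveat because spontaneous deamidation is frequent before glycine. A sequon
running past the peptide's C-terminus is `indeterminate_terminal` (the
protein context is unknown) and does not pass. Multi-deamidated peptides are
judged by their best site. Proteins absent from the membrane annotation are
excluded and counted.

## Glycan arithmetic and glycomics quantification

Residue masses are exact monoisotopic sums over elemental formulas
(Hex C₆H₁₀O₅, HexNAc C₈H₁₃NO₅, dHex C₆H₁₀O₄, NeuAc C₁₁H₁₇NO₈) with
CODATA/AME atomic masses; a free glycan adds one water, an alditol
(reductive β-elimination product) adds H₂ more. Charge math uses the proton
mass 1.007276 Da — not the hydrogen atom mass — in [M − zH]ᶻ⁻. PNGase-F
released N-glycans default to non-reduced, β-eliminated O-glycans to
reduced; both are overridable, since release chemistry, not the analysis,
fixes this.

Quantification follows the base-peak convention: the abundance of a
structure is the maximum intensity inside a ppm window around its
theoretical m/z across the run (no LC peak-area integration), expressed as
percent of the summed base peaks. The ppm tolerance defaults to 20 ppm — a
deliberate choice in the absence of a stated window, generous for ion-trap
survey scans, configurable everywhere it appears. The retention index on
peaks is carried as provenance but unused: it is a hook for future
chromatographic alignment, not part of the method.

Sialidase-based linkage inference compares relative abundances before and
after digestion: loss of ≥ `loss_fraction` (default 0.8) of a structure's
untreated abundance after sialidase S (α2-3-specific) calls α2-3; survival
of S but loss after sialidase A (α2-3/6/8) calls α2-6/8; survival of both is
reported as resistant/uncertain rather than forced into a linkage. The 0.8
default expects near-complete enzymatic removal while tolerating the
renormalization distortion that percent-of-total profiles incur when other
structures shift; no stated cutoff exists, so it is exposed in the API.

## Synthetic data: what it emulates and what it does not

Defaults are the stated world of the emulated design: 3 runs × 4 channels,
channels 114/115 mock and 116/117 ST3GAL4 (the real channel map is unknown —
it is explicit configuration, and the analysis only ever reads condition
labels from the design), 1:1:1:1 mixing via zero-mean channel shifts
(sd 0.5), protein log₂ abundances N(20, 2), peptide offsets sd 1, run
offsets sd 1, measurement noise sd 0.4, 10% of glycosites with a fixed
+1.5 log₂ effect, 10% NG-decoy sites with condition-independent deamidation,
80% membrane proteins, 5% missingness completely at random, 5% of PSMs
failing one random quality rule. Scale (60 proteins, 2–4 peptides each, 150
glycosites) is a desk-scale stand-in for the thousands of PSMs in a real
experiment, chosen once for runtime.

A green simulation test therefore establishes that the pipeline recovers the
*model it assumes*: additive log-scale artifacts, Gaussian noise, MCAR
missingness, effects confined to case channels. It does not establish
robustness to reporter-ion interference/ratio compression, isotope impurity,
intensity-dependent variance, interfering co-eluting peptides, or
non-random missingness — none of which the generator emulates.

The glycome generator emits peaks at theoretical m/z (charges 1 and 2) with
log-normal multiplicative noise of a given CV (mean-preserving,
σ² = ln(1+CV²)), and applies sialidase action by moving a structure's
intensity onto its desialylated composition according to the stated linkage
truth. It does not simulate isotope envelopes, in-source decay or LC peak
shapes.

## Numerical and interface choices

* Filter boundary semantics are literal: q ≤ 0.01 inclusive, Mascot ≥ 18
  inclusive, XCorr strictly greater than the charge cutoff; rejected PSMs
  are attributed to the *first* failed rule in the documented order, so the
  rejection counts partition the removed set.
* Deamidation tags on Gln are parsed and kept, but only Asn sites are
  glyco-candidates (PNGase F marks Asn, not Gln).
* Site numbering is 1-based over the protein sequence as supplied; no
  signal-peptide adjustment. Peptides occurring more than once in their
  protein yield all candidate sites flagged ambiguous; site mapping of an
  absent peptide is an error.
* Rank-product permutation count defaults to 10,000; the packaged
  simulation studies use 2,000 purely for runtime, which leaves the
  q ≤ 0.05 decisions stable (permutation p resolution 5·10⁻⁴).
* Seeds are mandatory in the simulator config and threaded through every
  stochastic step; identical seeds give byte-identical outputs.
* Matrices serialize as TSV with a multi-row header (sample / run /
  condition / channel); configs are YAML mirroring the two config
  dataclasses.

## Known limitations

* The union combination's Bonferroni factor of 2 is conservative when the
  two tests agree strongly (the usual case), costing a little power at the
  margin.
* π₀ smoothing by cubic polynomial is a pragmatic stand-in for the
  natural-spline smoother of the original q-value method; on small feature
  sets both are noisy, hence the fixed-λ fallback.
* The rank product assumes a complete feature × replicate ratio matrix;
  features missing an entire run are excluded from it (and hence from the
  combined test) rather than partially ranked.
* Protein rollup requires the accession mapping given in the input; no
  protein inference or grouping is attempted.
* Reporter intensities are taken as given; isotope-impurity correction and
  ratio-compression modeling are out of scope.
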
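# Methods

## The ΔZ statistic

For gene *g* in a contrast with treatment arrays *T* and control arrays
*C*, the pipeline computes ΔZ_g = (X̄_T,g − X̄_C,g) / σ_g, where X̄ are
arithmetic means of the replicate arrays and σ_g is the sample standard
deviation (n−1 denominator) of gene *g* across the entire reference
compendium merged with the experiment arrays. Expressing the change in
compendium-SD units borrows variance information from hundreds of
heterogeneous conditions, which a 3-replicate experiment cannot supply
on its own. A gene is called up when ΔZ > τ and down when ΔZ < −τ with
τ = 1 and a *strict* inequality: ΔZ exactly 1.0 is not significant.

Choices worth flagging:

- The replicates enter as a mean before differencing (mean-of-replicates
  rather than averaging per-replicate ΔZ values). For balanced designs
  the two differ only through σ's position outside the average; the
  mean-of-replicates reading is the standard one and is what is
  implemented.
- σ defaults to the *combined* compendium + experiment arrays and is
  computed once per run; computing it on the compendium alone is a
  one-line change at the call site (`per_gene_sd(compendium)`).
- Genes with σ = 0 cannot be scored; they are reported as `excluded`
  and listed in the compendium statistics table, never silently dropped.
  Constancy is detected from the value range, not from a floating-point
  zero test.
- No multiple-testing correction is applied to ΔZ calls. This is
  deliberate — the statistic is a fixed-threshold effect-size rule, not
  a p-value — but it means the per-comparison counts are not
  FDR-controlled, a caveat that matters when comparing counts across
  experiments.

## YbeY-dependence classification

The experiment contrasts wild type and a ybeY knockout, each with and
without hydroxyurea, giving four comparisons: C1 knockout-vs-WT
untreated, C2 WT HU response, C3 knockout HU response, C4
knockout-vs-WT under HU. An sRNA that is differentially expressed in at
least one comparison is classified **YbeY-dependent** when it is
significant in a genotype contrast (C1 or C4) *or* its HU-response
calls differ between genotypes (C2 call ≠ C3 call); sRNAs significant
nowhere are reported separately as not differential. This
operationalizes "the response depends on YbeY" as literally as the call
table allows; the rule is a pure function of the calls, so it is
insensitive to gene order and reproducible from the exported TSV alone.

## Sign concordance

For a cataloged signed pair (sRNA s, target t) and each comparison,
concordance requires dz_s·dz_t < 0 for repression and > 0 for
activation. By default both members must pass |ΔZ| > 1 (`tau_srna`,
`tau_target` in the policy); pairs failing the gate are "not counted"
rather than discordant, because an insignificant ΔZ carries no reliable
direction. The headline summary counts *unique* pairs concordant in at
least one comparison, not per-comparison sums.

## CLR network inference

Mutual information between two expression profiles is estimated by the
plug-in (maximum-likelihood) histogram estimator: each variable is
discretized onto B = 10 equal-width bins over its own observed range
and MI is computed from the joint cell frequencies in log base 2
(bits). The estimator is exactly symmetric (arguments are canonically
ordered before binning), non-negative, and returns 0 for a
zero-entropy (constant) profile. Equal-width binning makes MI invariant
under affine rescaling of either variable; it is *not* invariant under
general monotone transforms, unlike rank-based estimators. A warning is
emitted below 20 samples, where the plug-in estimator's positive bias
(~(B−1)²/(2n ln 2) bits) dominates.

CLR corrects each MI value against two backgrounds: the regulator's MI
against all genes (row) and the target's MI against all regulators
(column). Both z-scores are clipped at zero and combined as
score = √(z_reg² + z_tgt²). The backgrounds are regulator-restricted —
the full gene×gene MI matrix is never formed — which matches an
sRNA-focused network and keeps the cost at
O(n_srnas × n_genes × n_arrays). Zero-variance backgrounds contribute a
z of 0 with a warning. Self-pairs are excluded throughout.

Significance is assessed against a pooled permutation null: each
regulator's profile is shuffled across arrays (destroying its joint
structure with every gene while preserving its marginal), MI is
recomputed against all targets, and the permuted values are scored
against the *unpermuted* background statistics. p-values use the
add-one estimator p = (1 + #{null ≥ obs}) / (1 + N_null), which cannot
return 0 and whose resolution is set by N_null = n_perm × n_srnas ×
(n_genes − 1); with 20 sRNAs, 200 genes and 20 permutations the
smallest attainable p is ~1.3e-5. Benjamini–Hochberg adjustment over
all candidate edges gives q-values; the network keeps q < 0.005.

Recovery against planted truth reports precision and recall of the
q-thresholded edge set (precision is NaN when nothing is significant)
and AUPR over the full score ranking, integrating the
precision–recall curve trapezoidally after keeping, at each tied
recall level, the best attainable precision.

## Heatmap ordering

Rows are standardized to zero mean and unit sample variance, then rows
and columns are clustered by complete-linkage agglomeration on
Euclidean distances (scipy); columns are clustered on the
row-standardized values without column-wise scaling. Leaf order follows
scipy's convention (children ordered by cluster id, left-first
traversal), which the test suite pins against an independently coded
agglomeration trace. Ties in merge distance are broken by scipy's
cluster indexing; permuting input rows can therefore permute tied
subtrees, which is documented rather than hidden.

## The synthetic generator

The generator emulates the study's data shapes: an RMA-like log2
compendium across heterogeneous conditions (defaults: 759 arrays, 54
sRNAs, a 4300-gene complement) and a 2 genotype × 2 treatment × 3
replicate experiment. Its model, all in log2 units:

- each row has a baseline ~ N(8, 2²), typical of RMA intensities;
- an sRNA in compendium array *a* is baseline + condition factor
  (SD 1.0, the biological variability that makes compendium-wide MI
  informative) + measurement noise (SD 0.25, a typical replicate-level
  RMA dispersion; the defaults are asserted, not fitted, since
  replicate variance of the original arrays is unpublished);
- a planted edge makes its target track the regulator's realized
  deviation linearly with slope ±β (default 1.0), repression with
  probability 0.7; unregulated genes get their own condition factor;
- in the experiment, condition factors are replaced by a per-sRNA HU
  response ~ N(0, 1) shared by both genotypes, plus — for sRNAs flagged
  YbeY-dependent — a genotype×treatment interaction shift of magnitude
  3β (sign random) in knockout+HU arrays only. Targets inherit both
  through their edges; unregulated genes vary only by replicate noise.

sRNA expression is generated first and targets are linear functions of
the realized sRNA deviations, so edge recovery by correlation/MI is
analyzable; YbeY dependence as a pure interaction term reproduces the
operational signature the classifier looks for (discordant HU response
between genotypes) without asserting any mechanism. Hfq flags are
labels only; they do not change the generative model.

What the generator does **not** emulate: probe-level effects and RMA
itself (the pipeline consumes normalized matrices), batch structure,
correlated condition factors between genes, heavy-tailed noise,
indirect/cascade regulation, and sRNA–sRNA regulation. Passing the
benchmark scenarios therefore shows the machinery is correct and
well-calibrated under linear planted signal, not that real compendia
meet those assumptions.

Determinism: a single master seed spawns three independent sub-streams
(edge structure, compendium, experiment), so identical configs give
bit-identical outputs and regenerating the experiment never perturbs
the compendium.

## Benchmark scenarios

`srnaclr.benchmarks` fixes three standing scenarios, shared by the test
suite and the acceptance script:

- **Null FDR**: 20 sRNAs × 200 genes × 100 arrays, no planted edges,
  20 permutations; the fraction of q < 0.005 edges is the empirical
  false-discovery rate.
- **Planted recovery**: 20 sRNAs × 10 targets each against a 2000-gene
  background (regulon overlap kept rare), β = 1 vs noise SD 0.25, 100
  arrays, all sRNAs YbeY-dependent so every regulon is perturbed in the
  experiment; scores AUPR, precision/recall at q < 0.005, and
  sign-concordance recall.
- **Classification**: 20 sRNAs, half flagged YbeY-dependent, interaction
  shift 3β; recall of the planted flags from the call table alone.

The acceptance script runs these at 5/10/25 seeds respectively — sizes
chosen so the whole report recomputes in well under a minute while the
stochastic metrics are stable to a couple of percent across master
seeds — and additionally recounts the packaged study fixtures
(per-comparison sRNA lists, Hfq partition, with-targets lists).

## Known limitations

- The packaged fixtures transcribe the published lists verbatim,
  including their internal discrepancies: ArcZ and CydC appear in the
  Hfq-classified list but in none of the four per-comparison lists, and
  "RyrC" appears only there (plausibly RyeC). The fixtures preserve the
  lists as printed; nothing resolves or reconciles them.
- The genome-scale headline numbers of the original study (thousands of
  differential genes, the 664-target network, the 57 concordant pairs)
  depend on its raw arrays and external compendium and are out of reach
  here; the package validates the *procedure* on synthetic truth and the
  *bookkeeping* on the published lists.
- Equal-width-bin MI is the baseline estimator; spline-weighted or
  rank-based estimators would be drop-in alternatives behind
  `mutual_information` but are not implemented.
- ΔZ assumes the compendium σ is an honest yardstick for the experiment;
  platform or normalization mismatches between experiment and compendium
  would bias every call in a comparison coherently.
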
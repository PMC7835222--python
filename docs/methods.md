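# Methods

## Conservation scoring

Per-column conservation is the base-2 Jensen–Shannon divergence between the
column's amino-acid distribution and a background distribution representing
sites under no evolutionary pressure — the marginal amino-acid frequencies
underlying the BLOSUM62 substitution matrix, shipped as packaged constants
(leucine is the most frequent at 0.099; the vector is renormalised to sum
exactly to one). Base-2 JSD is symmetric and bounded in [0, 1]; a fully
conserved column scores between ≈0.76 (leucine, the most background-likely
residue) and ≈0.95 (tryptophan), while a column drawn from the background
scores near 0 for deep alignments.

Column distributions are estimated with:

* **position-based sequence weighting** (on by default): for column *c*
  with *r<sub>c</sub>* distinct symbols (gap counts as a symbol) of which
  sequence *i*'s symbol occurs *s<sub>ci</sub>* times, sequence *i*'s raw
  weight is the mean over columns of 1/(r<sub>c</sub>·s<sub>ci</sub>),
  normalised to sum to one. Ten extra copies of one sequence shift weighted
  region-mean scores by <0.02 where unweighted scores shift substantially
  (a tested property).
* **pseudocount** ε = 10⁻⁷ added per residue (keeps distributions strictly
  positive without visibly distorting them; configurable).
* **gap handling**: gaps are excluded from the 20-letter distribution and
  penalised linearly — the raw score is multiplied by (1 − weighted gap
  fraction), so an all-gap column scores exactly 0. In lenient parsing
  mode, ambiguity codes are likewise excluded from frequency counts.
* **window smoothing**: S′<sub>c</sub> = (1 − λ)·S<sub>c</sub> + λ·mean of
  raw scores over columns within ±w of *c* (excluding *c*, truncated at
  alignment edges), with w = 3 and λ = ½. Only the window radius is a
  commonly quoted setting; the ½ blend and the remaining constants follow
  the standard published defaults of JSD conservation scoring and are
  recorded in every profile header.

Reference coordinates: profiles map each non-gap column of a designated
reference sequence to residue numbers 1..L; all user-facing residue numbers
and regions are 1-based inclusive.

## Ortholog curation

Percent identities come from an in-package affine-gap global aligner (Gotoh
three-state recurrence) so curation is self-contained, deterministic, and
exactly testable against path enumeration. Conventions, chosen because
identity and gap conventions vary between tools and are rarely stated:

* defaults BLOSUM62, gap open 11, gap extend 1; a gap of length k costs
  open + (k−1)·extend;
* identity = identical-residue columns / all alignment columns (gap columns
  count against identity);
* traceback tie-break prefers diagonal over up over left, making alignments
  unique;
* strain deduplication keeps, per species key (organism name lower-cased,
  first two tokens), the record with the highest identity to the query,
  ties broken by longer sequence then lexicographically smaller id;
* one-to-one assignment requires the best candidate's identity to the query
  to **strictly** exceed its identity to every supplied query paralog;
  equality rejects with reason `paralog_closer`.

Partner presence is defined operationally: the supplied partner-organism
list (organisms in which a one-to-one partner ortholog was detected) is
treated as authoritative, and its complement as partner-negative. Absence
of detection and true absence cannot be distinguished from sequence data
alone; this assumption is recorded in output headers.

## Coevolution test

The statistic is the mean windowed-score difference (partner-positive minus
partner-negative) over the region of interest, paired per reference
residue. Defaults: region 336–501 (the C-terminal interaction region of
human ALDH1A1), with 371–501 (the two-hybrid clone boundary) as a named
preset.

Significance is assessed two ways, and both are always reported because no
single canonical test exists for this comparison:

* **Label-permutation test** (primary): organism rows from both alignments
  are pooled and reassigned to the two sets N = 999 times preserving set
  sizes; profiles and the delta are fully recomputed per permutation; the
  two-sided p is (1 + #{|Δ*| ≥ |Δ_obs|})/(N + 1), so the attainable floor
  is 1/(N+1). The reference sequence is included in both alignments as the
  coordinate anchor and stays fixed under permutation. The test requires
  both alignments to share one column space (equal column counts) — true
  for the simulated families and for profiles cut from a joint alignment;
  independently built MSAs with differing gap structure cannot be permuted
  this way. Permutation recomputation is restricted to the region ±window
  columns (weights still use all columns), which is exactly equivalent to
  the full profile and keeps 999 permutations under a second at the default
  problem size (60 organisms × 200 columns).
* **Wilcoxon signed-rank** on the per-residue deltas (exact null by
  sign-assignment convolution for n ≤ 25, tie-corrected normal
  approximation with continuity correction above). Residues are spatially
  correlated by the window, so this p is a complement, not a replacement,
  for the permutation p.

Measured calibration: with no planted signal the permutation test rejects
at α = 0.05 at the nominal rate (6.7% over 60 null simulations in the
development runs; the acceptance suite bounds it at ≤ 2/20 seeds).

## Statistical core

All tests are two-sided. Fisher's exact 2×2 uses the "probability ≤
observed" rule with a 1+10⁻⁷ relative slack, summed in log space — the most
common two-sided convention, stated because the convention is often left
implicit. The rank-sum test is exact (cached subset-sum DP over rank
assignments) for combined n ≤ 20 without ties, otherwise a midrank normal
approximation with tie-corrected variance and 0.5 continuity correction;
the branch taken is recorded in the result. The t test defaults to Student
pooled-variance with Welch behind a flag, since figure legends that say
"t test" rarely specify; both are labelled. Benjamini–Hochberg is the
standard step-up with q clipped at 1. Exact branches are validated against
full enumeration; the approximate branches agree with the exact ones within
0.02 at the switchover, and the rank-sum test's type-I rate is calibrated
to 5% ± 2% over 5000 null replicates in the suite.

## Expression directionality

Condition classification demands, for every regulator in the rule, presence,
significance (adjusted p ≤ 0.05 by default when loading `padj` columns),
and the required fold-change sign; anything else yields `unclassified` with
a per-gene diagnostic. Target intersection keeps the requested direction
class present in every table; a class with fewer than `min_class_size = 6`
members is excluded with reason `class_too_small` — a handful of genes
cannot support a distributional comparison (the motivating dataset has only
5 literature down-targets). An exact-zero fold change counts as "up" and is
flagged; zeros are vanishingly rare in continuous fold-change data but the
dichotomy must be total. Gene symbols match case-insensitively with a
collision check; synonym/alias resolution is out of scope.

## Kinetics

The standard curve is fitted with an intercept by default (forcing through
the origin is a flag), and absorbance series must be calibrated before rate
fitting — mixing units is a hard error. "Initial velocity" is the OLS slope
over the first 6 points (0–10 min at the 2-min cadence), a labelled
parameter rather than a hidden constant because the linear-phase window is
an experimental judgement; it can be set by point count or time bound.
Replicate SD uses the n−1 denominator; percent inhibition is
100·(rate_ctrl − rate_cond)/rate_ctrl; dose series get a Spearman
monotonicity diagnostic.

## Synthetic data

The generators define the study conditions; their defaults are the
conditions under which every recovery claim is tested.

* **Ortholog families**: reference drawn uniformly over the 20 amino acids,
  200 residues; 30 partner-positive and 30 partner-negative organisms; each
  organism sequence derived by independent per-site substitution, uniform
  over the 19 alternative residues — substitution probability 0.02 inside
  the planted 30-residue interface (residues 101–130) for partner-positive
  organisms and 0.3 everywhere else; 4 strain duplicates sharing a species
  key with a host organism; a human paralog decoy at divergence 0.5. No
  indels (the conservation signal is columnwise; gap handling is tested
  with hand-built fixtures), no substitution-matrix weighting (keeps
  analytic oracles exact), and no phylogenetic correlation — sequences are
  conditionally independent given the reference, so real-data effects of
  shared ancestry (inflated effective conservation, non-exchangeable sets)
  are outside what these tests demonstrate.
* **DE tables**: 33 shared up-targets, 300 null background genes at
  Normal(0, σ), σ = 1.5, regulators set exactly (enzyme log2FC +3.8 / +1.4
  in the two conditions per the motivating datasets; partner magnitudes
  −1.2/+1.1 are generator choices with only the sign constrained by the
  condition definitions). Target fold changes plant both the median and the
  directionality: a fixed count round(p·n) of targets (p = 0.70 up in
  condition A, 0.73 down in condition B) is concordant, drawn as a folded
  normal whose location is solved analytically so the planted mixture
  median equals ±2.5/−2.6; the remaining targets are discordant with small
  wrong-sign values (half-normal, scale 0.4), mirroring real tables where
  wrong-direction targets respond weakly. A pure Normal(μ, σ) mode
  (`p_up_pos=None`) is retained. A plain normal cannot show a median of 2.5
  with only 70% positive values, and symmetric wrong-sign magnitudes would
  cap the rank-sum separation well short of what the planted effect must
  deliver — the weak-discordant mixture is the simplest shape consistent
  with all three observed features. Five down-targets are included solely
  to exercise the small-class exclusion.
* **Time courses**: concentration(t) = v·(1 − inhibition)·t + N(0, 0.2 µM),
  31 points at 2-min cadence over 60 min, 3 replicates, v = 1 µM/min,
  default inhibition 0.3; optional conversion to absorbance with the NADH
  extinction slope 0.00622 AU/µM (6.22 mM⁻¹cm⁻¹ at 340 nm, 1 cm path).

All generators draw from a single explicitly seeded `default_rng` stream
per call; identical config + seed reproduce byte-identical outputs.

## Numerical notes and degenerate inputs

* All-gap columns: uniform placeholder distribution, gap fraction 1, score
  exactly 0; flagged as degenerate at parse time.
* JSD inputs must sum to 1 within 10⁻⁶; zero-probability terms contribute 0.
* Permutation p never reported below 1/(N+1); N < 19 is rejected (p floor
  too coarse to mean anything).
* Degenerate directionality comparisons (identical vectors) report p = 1
  with a flag instead of failing.
* All tabular outputs carry `#`-prefixed headers with the tool version,
  config hash, seed, and parameters; reruns with the same seed are
  byte-identical (a tested contract).

## Problem sizes used in the checks

Oracle equivalences run at enumeration-feasible sizes (alignment pairs up
to length 6, Fisher margins ≤ 12, rank-sum n ≤ 10, 200–1000 fuzz cases
each). Recovery studies run at the study conditions above with 999
permutations and 10–20 seeds per claim; the full suite and the acceptance
script each complete in well under a minute of compute per block on one
CPU.

## Known limitations

* Phylogeny is ignored throughout: the permutation test treats organisms as
  exchangeable, which real ortholog sets are not; a tree-aware null would
  be needed for strong claims on real data.
* Partner "absence" is detection-based and taken from the input list as
  authoritative.
* The expression analysis consumes precomputed DE tables; it does not call
  differential expression, resolve gene synonyms, or model inter-dataset
  batch effects.
* Kinetics covers initial rates and relative inhibition only — no
  Michaelis–Menten or inhibition-constant fitting, no baseline drift
  correction.
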
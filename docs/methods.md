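# Methods

## Data model and arm arithmetic

A karyotype record carries, per sex, the diploid number 2n, the fundamental
number NF (total chromosome arms), the fraction of acrocentric chromosomes,
and the sex-chromosome system (`X1X2Y`, `XY1Y2`, or `simple`).  Chromosome
shape categories follow Levan's nomenclature collapsed to two arm classes:
metacentric and submetacentric → *biarmed* (two arms); subtelocentric,
telocentric, acrocentric → *acrocentric* (one arm).  Hence
2n ≤ NF ≤ 2·2n, the biarmed count is NF − 2n, and the acrocentric fraction
can be estimated as (2·2n − NF)/2n.

The **printed fraction column is the authoritative analysis input**; the
(2n, NF) estimate is kept as a diagnostic only (`audit_table`, default
flag threshold 0.02).  The packaged compilation shows why: the *Gazella*
rows (e.g. 2n=30, NF=60, printed fraction 0.06) are inconsistent with the
two-arm convention because their source papers scored NF differently, and
silently recomputing would alter the compiled data.  On the packaged table
35 of 41 rows agree with the arm estimate to within 0.01.

All analyses are run on the female karyotype; male columns are stored and
selectable (`sex="male"`), and give the same qualitative conclusions.

The packaged table transcribes its published source verbatim, including one
genus-spelling inconsistency (*Carollia subrufa* vs *Carolia
perspicillata*) and an arithmetic quirk of the source prose: the text
claims 19 X1X2Y species but its own table prints 18 rows.  The loader logs
this; nothing is patched.  One published consequence: a species-level
Mann–Whitney run on the printed rows yields Umin = 24.5 rather than the
source's 25.5 (and Z = −4.80 rather than −4.88), exactly as expected if one
species is missing from the printed table.  These two numbers are therefore
cross-checked against an all-pairs enumeration oracle rather than against
the printed values.

## Rank tests

Both tests are implemented from first principles so the inferential core
depends on no statistics package; scipy appears only in the test suite as
an independent oracle.

**Mann–Whitney.**  U1 = Σ over cross-group pairs of [a > b] + ½[a = b]
(computed in rank-sum form, identical to the all-pairs count); the reported
statistic is Umin = min(U1, U2).  The normal approximation uses the
tie-corrected variance
Var(U) = (n₁n₂/12)·[(n+1) − Σ(t³−t)/(n(n−1))] with t the pooled tie-group
sizes, and **no continuity correction** — the most common textbook
convention, stated here so the standardised Z is reproducible.  When the
variance is zero (all values tied) Z = 0 and p = 1.

**Exact Wilcoxon signed-rank.**  Zero differences are dropped (their count
is reported), absolute differences are midranked, S = min(W+, W−).  For up
to 20 informative pairs the two-sided p is exact:
p = Pr(min(W+, W−) ≤ S) over all 2^n equally likely sign assignments.  The
enumeration is carried out through the generating function ∏(1 + x^{2rᵢ})
of the (integer-doubled) rank-sum distribution — a lossless dynamic-
programming form of full enumeration, verified in the tests against the
literal 2^n loop for n ≤ 12.  Overlapping upper/lower tail regions (possible
when S ≥ T/2) are counted once.  Above the cutoff (configurable; default 20,
≈10⁶ assignments) a tie-corrected normal approximation is used and the
result is labelled `normal_approximation`.

With nine same-sign differences the exact two-sided p attains its floor
2/2⁹ = 0.00390625 (printed 0.0039).  One informative pair gives p = 1: both
sign assignments are extremal.

## Phylogenetic correction

**Cluster units.**  Tips sharing one multiple-sex-chromosome system are
collapsed into *maximal monophyletic same-system sets*, found bottom-up
from the tip systems.  Tips labelled `simple` participate in the monophyly
computation (they break up clades) but form no units.  On the packaged tree
the units are genus-level — six *Gazella*, six *Taterillus*, the genus
*Mus* split into two opposite-system singletons — with one documented
exception: the four X1X2Y platyrrhine genera (*Aotus*, *Alouatta*,
*Callimico*, *Cacajao*) are jointly monophyletic and therefore merge into a
single nine-member unit.  That merged unit takes part in no packaged pair,
so no headline quantity depends on it.  A unit's representative value is
the mean of its members' fractions, or (resampling mode) one member drawn
uniformly with a seeded generator.

**Independent pairs.**  A contrast pair joins one X1X2Y unit with one XY1Y2
unit; a pair set is phylogenetically independent when the tree paths
connecting the two units of each pair share no edge, which
`validate_pair_independence` checks explicitly by path intersection.  The
packaged nine-pair configuration reconstructs the reference analysis:
congeneric *Mus*–*Mus*; within-family Bovidae
(*Tragelaphus*–*Gazella*), Phyllostomidae (*Choeroniscus*–*Carollia*,
*Mesophylla*–*Artibeus*), Muridae (*Vandeleuria*–*Taterillus*), Macropodidae
(*Lagorchestes*–*Wallabia*); and three deeper contrasts
(*Deltamys*–*Sorex*, *Herpestes*–*Muntiacus*, *Choloepus*–*Potorous*).  The
exact composition of such figure-derived pairings is underdetermined at the
family level, so the configuration file is editable, and an automatic
pairing algorithm is provided as an alternative: post-order traversal,
pairing the closest unpaired cross-system units (node-count patristic
distance — branch lengths are never required — ties broken lexicographically
by unit id) and retiring every unit inside the paired subtree, which
guarantees edge-disjoint paths by construction.  All paired-test output
records which pairing was used.  On the packaged data both pairings yield
nine pairs and the same test result, because every X1X2Y unit's value
exceeds its partner's.

**Resampling.**  K iterations (default 100, seeded); in each, every unit is
represented by one uniformly drawn member (draws consume the generator in
sorted-unit-id order, making results independent of pair order), and the
exact signed-rank p is recorded.  The summary is mean ± SE with
SE = sample SD/√K (the standard-error-of-the-mean reading of "mean ± SE").
Every iteration's p is bounded below by 2/2⁹; the mean exceeds the floor
exactly when some draw flips a pair's sign.  On the packaged data two pairs
can flip (*Taterillus arenarius* 0.80 > *Vandeleuria* 0.59; *Gazella
gazella* 0.29 > *Tragelaphus* 0.19, each drawn with probability 1/6), so
the resampled mean sits slightly above the floor (≈0.008 at K=100), in the
same order of magnitude as published values of this quantity.

## Histograms

Acrocentric-fraction histograms use bin width 0.1 with half-open bins
[lo, hi) and the final bin closed at 1.0 — a plotting convention, not an
analysis input.  An optional user-supplied background compilation in the
same TSV schema is binned identically; none is packaged.

## Synthetic data generator

The generator operationalises the drive hypothesis so the pipeline can be
calibrated without real data.  It is deliberately minimal machinery, not a
population-genetic model: no effective population sizes, no underdominance
of fusion heterozygotes, no inference of drive from data.

* **Tree:** Yule pure birth, rate λ (default 1), n tips (default 48),
  hand-seeded and bit-reproducible.
* **Karyotype state:** A acrocentric and B biarmed autosome pairs
  (defaults A₀=16, B₀=4: an acrocentric-rich ancestral karyotype, the
  standard view for mammals and, under the availability weighting below,
  the only starting region from which both ends of the fraction range are
  reachable on realistic branch lengths).
* **Rearrangements:** Poisson(ρ·t) attempts per branch (ρ default 6).  An
  attempt proposes a fusion (two acrocentric pairs → one biarmed pair) or a
  fission (the reverse), with probability proportional to availability:
  A(A−1) against B.  A fusion fixes with probability σ(2d) = 1/(1+e^(−2d)),
  a fission with σ(−2d).  Arm count A+2B is conserved by every event; only
  2n changes.
* **Drive coefficient d:** inherited along lineages, redrawn at a branch
  with probability 0.15 from the two-component mixture {+d₀, −d₀} (d₀
  default 3; weight ½ each).  The logistic map is the simplest symmetric
  monotone map from a signed bias to a fixation probability, with d = 0
  recovering neutrality (½).  The mixture drives lineages toward the two
  ends of the fraction range and reproduces the bimodal pooled distribution
  seen in real mammal compilations; with d = 0 the pooled distribution is
  unimodal.
* **Sex-system assignment:** fusion events arise at rate μ·A/(A+B) per unit
  branch (mutational supply comes from acrocentrics; μ default 1),
  evaluated at branch-start state (rate resolution is one branch).  An
  event is an X- or Y-fusion with probability ½.  An X-fusion must pass
  female meiosis and fixes with probability σ(2d); a Y-fusion is
  male-limited and fixes with probability ½.  The first fixed event sets
  the lineage's system permanently (absorbing, matching one-system-per-
  species data) and consumes one acrocentric pair, reflected in the
  emitted tip karyotype.
* **Emission:** female 2n = 2(A+B)+2 and NF = 2(A+2B)+2 (biarmed sex pair
  convention — a constant offset only); the printed fraction is exactly
  A/(A+B); males carry one chromosome fewer (X1X2Y) or more (XY1Y2) with NF
  clamped into the arm bounds, mirroring published tables.  Emitted tables
  pass strict validation and round-trip identically.

What the simulator does **not** emulate: real fundamental-number convention
noise (the *Gazella*-style audit failures), uneven taxon sampling,
correlated rate variation, and any quantitative drive-strength calibration.
Passing calibration tests therefore demonstrates the pipeline's statistical
correctness under the model's assumptions, not biological realism.

## Calibration experiments

**Type-I error.**  Under the null (d = 0: fusion, fission, and X/Y fixation
probabilities all ½, so system type is independent of karyotype), datasets
are simulated, clustered, auto-paired, and tested in cluster-mean mode; the
rejection rate at α = 0.05 over 1000 replicates must sit within 3
Monte-Carlo standard errors of 0.05.  Replicates are conditioned on
producing at least 7 independent pairs (`min_pairs`): the exact test's
attainable p-values are multiples of 2/2^k, so with fewer than six pairs it
can never reject at 0.05 and an unconditioned experiment would measure
pair-count attrition rather than test size (attainable sizes: 0.031 at
k = 6, 0.047 at k = 7, 0.039 at k = 8–9).  The null conditions
(`SimParams.null_calibration()`: 192 tips, μ = 1) are sized so enough
cross-system units form; the experiment runs in about a minute on one core.

**Sign recovery.**  Under drive heterogeneity the fraction of replicates in
which the X1X2Y group is more acrocentric than the XY1Y2 group rises with
the drive magnitude.  The calibration grid is {0, 1, 3} with 200 replicates
per point and common random numbers across points: the zero-effect control
sits at ½, and recovery is checked to be nondecreasing along the grid.
Above d ≈ 1.5 recovery saturates near 0.85 — residual misses come from
replicates with few fused tips — so grid points are placed on the rising
part of the response, where ordering is informative.

## Numerical and engineering choices

* Fractions are stored at full precision; comparisons to 2-decimal printed
  values accept round-half-up within 0.005 or floor-truncation, both of
  which occur in published tables.
* All randomness flows from explicit seeds (numpy `default_rng`); reports
  are byte-identical across reruns with the same configuration and seed,
  and all statistics are invariant to input row order.
* Strict loading fails on any invariant violation, listing offending rows;
  permissive mode keeps and logs them.  CLI exit codes: 0 ok, 1 validation
  failure, 2 runtime error.
* Degenerate inputs: a zero-variance Mann–Whitney gives Z = 0, p = 1;
  all-zero differences are an error ("no informative pairs"); an empty
  cluster unit is an error; automatic pairing of single-system data returns
  an empty pair list with a warning.

## Known limitations

* The nine-pair configuration is a reconstruction constrained by family
  structure; alternative family-consistent pairings give the same S = 0
  result but can shift the resampled mean p within its order of magnitude.
* The simulator's branch-resolution fusion rate and logistic fixation map
  are stand-ins; none of its parameters are biologically calibrated.
* The maximal-monophyly cluster rule merges adjacent same-system genera
  (the platyrrhine case above) — correct under the stated definition, but
  coarser than a strictly genus-level reading.
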
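# Methods

This note documents the models, conventions and numerical choices behind
`socspat`, and what the synthetic-data tests do and do not establish.

## Study design assumed by the pipeline

Observations are instantaneous scan samples at 15-minute frequency over
two daily blocks, 09:00–12:00 and 15:00–18:00 (13 + 13 = 26 scans/day;
12:00 belongs to the morning block).  Positions are digitised to 1-m grid
cells on a 30 × 30 m map and stored as cell-centre coordinates, so
sub-metre precision is never implied.  The feeding-zone door centroid
defaults to (5.5, 3.5) — the centre of the door polygon on the map — and
is configurable.  Out-of-sight individuals are explicit rows with
`visible = False`, never absences: "not scanned" and "in the forest" are
different facts and the F20M definition needs the distinction.

Individuals younger than 5 years are excluded (inclusive threshold:
age ≥ 5 is retained).  Missing ages are imputed with the mean age of the
individual's age class; the subadult/adult boundary is not part of the
field protocol and is set here to 5–7 vs ≥ 8 years (config key
`subadult_max_age`).  Individuals with an undefined dominance score (no
agonistic interactions) are dropped from all statistical models, not from
the descriptive networks.

## Spatial metrics

F10M is a *relative* frequency: afternoon scans within 10 m of the door
divided by afternoon scans in which the individual was observed at all.
F20M is an *absolute* count: afternoon scans over 20 m from the door plus
afternoon scans out of sight.  The asymmetry is deliberate — the far
measure treats leaving the area as the extreme of being far from the
patch.  Observations between 10 and 20 m contribute to neither measure.
Boundary convention: d ≤ 10 m counts as "within", d > 20 m as "over";
ties at exactly 10.0/20.0 m follow these inclusive/exclusive choices.
Only afternoon scans are used by default (`spatial_period`), because food
delivery was reliable only at the end of the afternoon block and that is
when feeding competition is expected.  The F10M denominator counts
afternoon scans only; `f10m_denominator: all` switches to all observed
scans for sensitivity.

SRF10M = √F10M is used in all models; the square root stabilises the
variance of the proportion.  Homoscedasticity diagnostics
(Breusch–Pagan, Bartlett) are reported with every variance partition but
never gate the analysis; the transform is applied unconditionally.

## Dominance

Only dyadic (two-participant), clear-outcome interactions count; when
several records share (timestamp, actor, receiver) they are treated as a
behaviour sequence within one bout and only the final record counts.

The dyadic dominance index D_ij = P_ij − (P_ij − ½)/(n_ij + 1) shrinks
win proportions toward ½ for sparsely observed dyads; non-interacting
dyads get D = 0.  The modified David's score is
DS_i = w_i + w2_i − l_i − l2_i with w_i = Σ_j D_ij, w2_i = Σ_j D_ij w_j
and l, l2 the mirror sums; scores sum to zero by construction.

Linearity uses Landau's h = 12/(N³−N) Σ_i (V_i − (N−1)/2)², with V_i the
number of individuals i dominates; observed ties contribute ½ to both
parties and stay fixed.  Unknown relationships (n_ij = 0) contribute ½
each and are corrected by h′ = h_ties + 6u/(N³−N), the expectation of h
when each unknown dyad is resolved by a fair coin.  Significance comes
from a two-step randomization: per iteration the observed matrix's
unknowns are resolved at random and compared against a fully random
tournament of the same size; p is right-tailed with the observed
comparison counted once.  Note that small groups cannot reach
significance regardless of structure (a random 4-individual tournament is
perfectly linear 37.5% of the time).

## Association networks

A dyad is associated in a scan iff the pairwise distance is ≤ 1 m
(inclusive; roughly one adult body length, the range of touch
interaction).  Association is strictly pairwise — no gambit-of-the-group
chaining — because the definition is dyadic distance, not party
membership.  The affiliative network uses all scans (both blocks); the
5-m co-occurrence network (everyone within 5 m of the door in the same
scan, pairwise associated) uses afternoon scans, matching the spatial
metrics.  The "zone-excluded" affiliative network drops associations
whose two members are both within 5 m of the door in that scan; it is the
comparison network for asking whether feeding-zone co-occurrence mirrors
associations elsewhere.

HWI = x/(x + y_AB + ½(y_A + y_B)) corrects for unequal observability;
dyads never sampled (neither member ever observed) are undefined and
enter matrix models as 0.

### Non-random association test

H0 is "no preferred or avoided companion": the null conditions on each
scan's observed individuals, its edge count and each individual's
within-scan degree, and rewires edges by double-edge swaps inside each
scan.  One long Markov chain is run across all scans: a burn-in of
`cv_burn_in_per_edge × E` attempted swaps (E = total edges, default
multiplier 100), then `cv_thin_per_edge × E` attempted swaps between
successive null samples so consecutive samples are decorrelated.  The
statistic is the CV of the HWI matrix over sampled dyads — preferred and
avoided companions inflate the spread of association indices.  This is a
swap-chain approximation to "permute associations within samples"; the
null hypothesis is identical, the mixing parameters are explicit.  The
HWI denominators are invariant under the swaps (who is observed never
changes), which makes each chain step O(1).

A caveat demonstrated by the generator tests: shared spatial preference
alone (two individuals independently drawn to the same area) creates
dyad-level association structure that this test will detect.  The clean
"no structure" null therefore requires switching off spatial attraction
as well as cohesion, and a significant result in real data means
"non-random co-location", with habitat use as one candidate mechanism.

### Communities

Subgroups come from Newman's leading-eigenvector method on the weighted
modularity matrix B = W − kkᵀ/2m: recursive bisection by the sign of the
leading eigenvector of the community's generalized modularity matrix,
refined by Kernighan–Lin node moves, accepting a split only when it
increases Q.  Because optimal k-way partitions need not nest inside
optimal bisections, a final greedy node-move phase (nodes may move
between or found communities) and a small number of deterministic
random-restart searches are run, keeping the best-Q partition; on graphs
of ≤ 8 nodes this is verified against exhaustive search.  Q > 0.3 is
reported as a "useful subdivision" following common practice.
Per-individual assignment certainty is the absolute leading-eigenvector
loading at the split that fixed the individual's community — a relative,
within-split measure, reported as 0 for individuals never split.

## Matrix inference

All p-values are permutation-based, two-sided unless a directional
hypothesis is stated, and count the observed arrangement once, so
p ∈ [1/(n_perm+1), 1].  Default n_perm is 10,000.  One-tailed directions
used by the pipeline: males > females in MDS; age positively correlated
with MDS; SRF10M positively and F20M negatively correlated with MDS.

Attribute matrices: absolute differences for age and MDS; same-sex = 1;
same-matriline (kinship) = 1.  A missing matriline becomes a singleton
matriline (no kin) and is flagged.

Mantel tests correlate off-diagonal dyads with a null from simultaneous
row/column permutation.  MRQAP uses Dekker's double-semi-partialing: for
each predictor, its matrix residual on the remaining predictors is
QAP-permuted and the partial statistic recomputed.  Because the exact
normalisation of a "partial r" is reported differently across packages,
both the standardized coefficient and the partial correlation are
reported; the permutation p is computed on the partial correlation (for
OLS with fixed df the two are monotonically related, so the p is the
same).  With one predictor DSP reduces exactly to plain QAP regression.

Variance partitioning regresses an outcome on a continuous block (MDS,
df = 1) and a categorical block (subgroup dummies, df = levels − 1);
semipartial r² of a block is R²(full) − R²(without the block), i.e. the
variance uniquely attributable to it — shared variance belongs to
neither block.  Significance permutes the response vector
(`permute: response`); a ter Braak-style residual-permutation mode is
available as a sensitivity option because the observation-permutation
versus residual-permutation choice is not settled for partial
regression.  For n ≤ 6 all permutation machinery is verified against
complete enumeration of the n! row/column permutations.

## Synthetic data generator

The generator emulates the study conditions: 39 adults (21 M / 18 F,
ages uniform 5–26), 9 matrilines, 24 days × 26 scans (≈ the 631 field
scans), attendance probability 0.16 (am) vs 0.30 (pm) so the mean number
of scans per individual (~144) matches the field value, and ~90 dyadic
agonistic interactions per day so each dyad averages ≥ 3 interactions —
enough for stable David's scores at N = 39.

Latent dominance is a·(male) + b·age + noise (a = 2, b = 0.1 per year,
noise SD 0.6), standardized.  Eight planted subgroups are unions of
whole matrilines, allocated largest-first to balance sizes: kin ties
never straddle a subgroup boundary, which keeps the kin-association
boost consistent with the planted community structure (a matriline split
across two subgroups would wire them together and make the "planted"
labels wrong by construction).  Each subgroup also holds a persistent
home direction — evenly spaced bearings from the door, shuffled across
subgroups — so two subgroups at similar door distances occupy different
sectors rather than colliding.  Per scan, each subgroup receives an
anchor point whose
expected distance to the door is `base_distance` (12 m — well inside the
~16 m a uniformly placed animal would average, since a provisioned group
crowds the food source) minus `door_attraction_slope` (6 m/SD) times the
subgroup's mean dominance, plus a per-subgroup constant bias (SD 4 m,
centred to mean zero across subgroups so it encodes *relative* spatial
preference and cannot push the whole group away from the door) and
scan-level noise; members
sit within ~1 m of the anchor with probability 1 − 1/`subgroup_cohesion`
(default 0.8), otherwise at an individually drawn distance with the
weaker `individual_attraction_slope` (1 m/SD).  Attendance is shifted on
the logit scale by 0.4 × the subgroup's mean dominance — subordinate
subgroups stay in the forest more, which is what makes F20M (which
counts out-of-sight scans) negatively dominance-related.  The cohesion
and kin multipliers are odds-style: a value of 1 is exactly neutral, so
null datasets are available by construction.  Positions are
truncated-normal around anchors, clipped to the square and digitised to
cell centres.  Agonistic winners follow a logistic in the dominance gap
(slope 1.5/SD); polyadic and unclear records are injected at 4% each as
*extra* rows so the filters can be audited against the injection counts.

The two attraction slopes are deliberately unequal: placement is
primarily a subgroup-level property (subgroup anchors carry both the
dominance gradient and subgroup-specific spatial bias), with only a weak
individual-level dominance pull.  This realises the structure the
analysis is designed to detect — rank-related access to the patch at the
group level, with subgroup membership explaining more of the spatial
variance than individual rank.

What the generator does **not** emulate: movement autocorrelation within
a day, observer visibility gradients, seasonal drift, grooming-specific
affiliation (1-m proximity is the proxy throughout), rank-distance
tolerance at the patch (the H3 MRQAP on synthetic data is therefore a
null-behaved control, not a planted effect), and demographic change.
Passing recovery tests shows the estimators recover the structure the
generator plants at field-realistic sampling effort; it does not
validate the behavioural assumptions themselves against real mandrills.

## Problem sizes and numerical choices

The test suite calibrates type-I error over ≥ 500 null replicates per
test at n_perm = 199 and checks the qualitative H1/H2 pattern over 50
study-scale replicates; the acceptance script runs the full pipeline at
n_perm = 2,000 with a thinned swap chain (burn-in 20 × E, thinning
0.5 × E) — sizes chosen so a complete run stays fast while keeping
Monte-Carlo error well inside the decision margins.  Permutation seeds
are explicit everywhere; the pipeline derives one sub-seed per analysis
stage from the master seed, so reruns are byte-identical.  Degenerate
inputs are defined rather than accidental: empty win matrices give D = 0
everywhere, zero-variance vectors and constant matrices raise errors,
scans with no permutable structure give p = 1 with a warning, and a
network with no zone dyads reports the overlap percentage as missing.

## Known limitations

* The swap-chain null is an approximation to exact uniform sampling of
  degree-constrained graphs; mixing is controlled by explicit parameters
  rather than proven bounds.
* Leading-eigenvector modularity with refinement is a heuristic; the
  exhaustive-search guarantee is only tested for small graphs.
* The h′ randomization treats observed ties as fixed; alternative
  conventions randomize ties as well.
* Subgroup labels feed H2 as if known; uncertainty in the community
  assignment is not propagated into the variance partition.
* Modularity has a resolution limit: small, spatially adjacent planted
  subgroups are occasionally merged when the merged partition scores an
  (essentially tied) equal Q, so replicate-level subgroup agreement has a
  tail slightly below perfect recovery.
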
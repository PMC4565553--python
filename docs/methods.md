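# Methods

`cardevol` re-implements, as one tested pipeline, the computational
procedures used to trace how a family of CARD (caspase activation and
recruitment) domains — the signaling modules of the RIG-like receptors and
of IPS1/MAVS — diversified and acquired new binding partners: ancestral
sequence reconstruction that integrates over tree-topology uncertainty,
simulation-based calibration of reconstruction error and of the branch-site
selection test, profile-HMM and similarity-network clustering of domain
subfamilies, duplication/loss rooting, a permutation screen for gene
conversion, and one-site binding-kinetics estimation.  No raw sequence or
instrument data ship with the package; every analysis is exercisable on data
from the synthetic generators, which define the study conditions for all
tests.

## Substitution models

**Protein.**  The LG replacement model with optional alignment-derived
("+F") frequencies and discrete-gamma rate variation.  The generator is
built as `Q_ij = s_ij * pi_j`, made proper and rescaled so one unit of
branch length is one expected substitution per site.  "+F" frequencies are
residue counts with a pseudocount of 1 per residue (so no frequency is
zero).  Rate variation uses `ncat` equiprobable categories represented by
their conditional means (not medians), computed from the incomplete-gamma
closed form; the default is 8 categories, with `alpha` free.

**Codon.**  A Goldman-Yang-style 61-state model: single-nucleotide changes
only, transition/transversion ratio `kappa`, nonsynonymous factor `omega`,
target-codon frequencies `pi_j` (F3x4 by default; F61 can be supplied).
Three parameterizations:

- one-ratio (M0): a single `omega`;
- sites: a fraction `p0` of sites with `omega0 < 1`, the rest neutral;
- branch-site model A: classes 0 and 1 as in the sites model plus classes
  2a/2b, in which a single *foreground* branch takes `omega2 >= 1` while
  the background keeps `omega0` or 1.  Class proportions follow the
  standard convention: `p2 = 1 - p0 - p1` split between 2a/2b in
  proportion `p0 : p1`.  The null model fixes `omega2 = 1`.

Mixture generators are scaled jointly so branch lengths are expected
substitutions per codon under the *background* class mixture; the same
scale applies to foreground matrices, keeping one time axis per tree.
`kappa` is a free parameter (ML-estimated, initialized at 2.0); the codon
frequency parameterization is configurable because tools differ on it.

Transition probabilities come from an eigendecomposition of the symmetrized
generator (`D^{1/2} Q D^{-1/2}`), which is exact for these reversible models
and lets one decomposition serve every branch length.  Tiny negative
entries from round-off are clipped and rows renormalized.

## Likelihood, optimization, and the foreground branch

Felsenstein pruning runs over the mixture (gamma categories or omega
classes) with per-node scaling, so 50+ taxon alignments do not underflow.
Gaps, `X` and ambiguous codons are missing data (partial vectors of ones).

Branches are identified by leaf-set bipartitions.  A bipartition can
correspond to more than one edge of a *rooted* tree — both root-adjacent
edges when the root lies on the branch, and any degree-2 chain created by
rerooting — and all matching edges are treated as the (single) foreground
branch.  This makes the branch-site likelihood invariant to root placement,
matching the unrooted semantics of the test.

Optimization is coordinate ascent: branch lengths in post-order, then
global parameters, each by a bounded Brent line search (positive parameters
on a log scale).  Bounds: branch lengths `[1e-8, 50]`, `alpha`
`[0.05, 20]`, `kappa` `[0.01, 30]`, omegas `[1e-4, 20]` (`omega0` capped at
1, `omega2` floored at 1), proportions `[1e-6, 1-1e-6]`.  A proposed move
is kept only when it improves the likelihood, so the lnL trajectory is
monotone; convergence is a sweep improvement below `tol` (default 1e-6,
looser in the large simulation experiments — see below) or a sweep cap.
For branch-site models the line searches use the derived coordinates
`(p0 + p1, p0/(p0+p1))` instead of raw `(p0, p1)`; the raw coordinates are
strongly correlated in the likelihood surface and triple the sweep count.
Eigendecompositions are cached per `(kappa, omega)` on the *unnormalized*
generator, with the mixture scale folded into the branch-rate multiplier,
so proportion moves cost no new decompositions.

## Branch-site test of positive selection

`branch_sites_lrt` follows the standard two-step scan: (1) branch lengths
and `kappa` are estimated once under M0 and then fixed; (2) the model-A
null is fitted, and the alternative is fitted starting from the null's
estimates with `omega2 = 1`, so `lnL_alt >= lnL_null` holds by
construction.  The statistic `2(lnL_alt - lnL_null)` (clamped at 0) is
referred to chi-square with df = 1 and Bonferroni-corrected across the
tested branches.  Because `omega2` sits on the boundary under the null, the
plain chi-square is conservative; the 50:50 chi-square/point-mass mixture
(which halves positive-statistic p-values) is available via
`boundary_mixture=True` but off by default, as the plain chi-square is what
a Bonferroni-corrected chi-square test means.

**False-positive-rate experiment.**  Codon data are simulated with no
positive selection anywhere under three regimes — `neutral` (omega = 1
everywhere), `sites` (the two-class constrained mixture on every branch),
and `branch_sites_released` (the sites mixture, with the tested branch
released to omega = 1; each tested branch gets its own dataset) — and each
replicate is analyzed with the same two-step procedure.  The FPR is the
fraction of replicate-by-branch tests significant after Bonferroni at
`alpha = 0.05`; both the per-replicate mean (with SE) and the pooled
fraction are reported, since the two denominators differ.  Desk-scale run
sizes are 50 replicates of 90 codons on an 8-taxon tree with 3 tested
branches (about 4 minutes on one CPU with `tol = 1e-4`); the replicate
count is configurable.  Empirical regimes default to `p0 = 0.8`,
`omega0 = 0.1` (logged) when no fitted sites model is supplied.

## Ancestral reconstruction

Marginal (empirical-Bayes) posteriors are computed per internal node and
site with an inside-outside pass per mixture component, combined with the
component weights on a per-site log scale; the per-site normalizer equals
the site likelihood at every node, which the tests exploit as an internal
consistency check.  MAP calls break ties by the fixed residue order
ARNDCQEGHILKMFPSTWYV.

**Topology uncertainty.**  Reconstructions from each tree in a weighted set
(weights = posterior probabilities, normalized at load) are integrated per
target clade: clades are matched across topologies by descendant-leaf-set
equality, posteriors are weight-averaged over trees containing the clade,
and the supporting weight fraction is reported.  Model parameters are
re-fitted per topology.

**Indels.**  Presence/absence (gap = 0) is reconstructed per site per tree
by Fitch parsimony; ambiguous sets resolve toward presence at the root and
toward the parent state below it.  Per-node presence probability is the
weighted fraction of trees (containing that clade) reconstructing presence;
calls use a 0.5 threshold with ties going to presence.

**Confidence summaries** report, per node and pooled over nodes, the
fraction of present sites with MAP posterior above 0.95/0.90/0.80, the
count of ambiguous sites (second-best posterior above 0.3), and the
fraction of those whose alternative residue falls in the MAP residue's
biochemical class.  The default 7-class grouping is {AVLIMC} {FWY} {STNQ}
{DE} {KRH} {G} {P}; it is configurable because such groupings are
convention, not measurement.

**Error calibration.**  Protein data are simulated along the fixed tree
under the supplied model (true internal states recorded), reconstructed
with the *generating* model (no re-estimation inside replicates), and
scored per node: strict error (MAP != truth) and class error (different
biochemical class).  Class error is bounded by strict error by
construction.  The tests verify zero error at zero divergence, error
reduction when branch lengths are halved (paired sign test), and that the
mean MAP posterior tracks empirical accuracy within 0.05 over >= 10,000
reconstructed residues — the empirical-Bayes posteriors are approximately
calibrated *under the generating model*; real data, where the model is
wrong, can be less well calibrated.

**Compositional stationarity.**  Each group's residue counts (gaps
excluded) are tested against expected counts from the pooled composition
by chi-square with df = 19.

## Topology test and rooting

The Shimodaira-Hasegawa test uses RELL bootstrapping: per-site
log-likelihoods per candidate topology (branch lengths optimized per
topology), site resampling without refitting, per-tree centering, and
`p = P(max-centered delta >= observed delta)` with ties counting toward
non-rejection; the best tree gets p = 1 by construction.  1000 replicates
by default (a convention, not a reported value).

Gene trees are rooted without outgroups by duplication/loss reconciliation:
every candidate root edge is scored by LCA-mapping the rooted tree into the
species tree, counting duplications (a node mapping to the same species
node as one of its children) and losses by the standard depth-difference
formula, with unit costs; all cost-minimizing edges are returned.

## Subfamily profiles and the similarity network

Per-subfamily profile HMMs are built from column slices of one master
alignment: columns at least 50% occupied become match states; match
emissions are counts with a 0.2 pseudocount per residue; transitions are
counted from each sequence's match/insert/delete path with +1 pseudocounts.
The distance between two HMMs is the mean positionwise symmetrized
Kullback-Leibler divergence of match emissions (transitions excluded —
alignment of unequal-length HMMs is deliberately avoided by the shared
coordinate system), and neighbor joining on the distance matrix clusters
the subfamilies.  NJ clamps negative branch-length estimates to zero,
moving the deficit to the sibling edge so the joined pair's summed distance
is preserved.

The similarity network scores all sequence pairs (gaps stripped) by
Smith-Waterman local alignment with BLOSUM62 and affine gaps costing
`11 + k` for a gap of length `k`; e-values use the Karlin-Altschul form
`K m n exp(-lambda S)` with the published gapped constants
`lambda = 0.267`, `K = 0.041` — an approximation of database-tool e-values
that is monotone in score, which is all the network construction uses.
Edges with e-value above 1e-3 are dropped.  Layout is left to external
viewers (the graph exports to GraphML/TSV with subfamily attributes).

## Gene-conversion screen

Alignment columns with no gaps and at least two states are the polymorphic
set.  For each unordered sequence pair, agreement at a polymorphic column
scores +1 and disagreement -1 (the mismatch penalty is configurable), and
the candidate conversion tract is the maximal-scoring contiguous fragment
(Kadane's algorithm), reported in original alignment coordinates with its
polymorphic-site count, length and mismatch counts.  Significance comes
from permuting the polymorphic-column order (vectorized prefix-sum scan
over all permutations).  Because the tract score is integer-valued, ties
between permutations carry substantial probability mass at screening
scales, and the classic `(1 + #{perm >= obs})/(n_perm + 1)` estimator is
then strongly conservative (its null mean is ~0.68 rather than 0.5 in our
measurements).  The default `sim_p` therefore splits tied permutations
evenly — `(#{>} + (#{=}+1)/2)/(n_perm+1)`, clamped below at
`1/(n_perm+1)` — which restores a uniform null while leaving clear signals
(tracts with essentially no tied permutations) unchanged; the conservative
count remains available via `estimator="upper"`.  Pairwise p-values are
Bonferroni-corrected over pairs.  Analytic Karlin-Altschul fragment
p-values are intentionally not implemented.

## Binding kinetics

The analysis mirrors a plate-based biolayer-interferometry workflow.
Traces (time, nm shift) per concentration/replicate/phase are
blank-corrected against the 0-concentration probe (per replicate, linear
interpolation across time grids).  The steady-state response is the mean of
the last 500 association samples (all samples, with a warning, for shorter
traces).  The initial rate is `A*k`, the t = 0 derivative of a
single-exponential association fit `A(1 - exp(-k t))`; a windowed
linear-slope estimator is available as an alternative.  Both
concentration-response curves are fitted with the one-site form
`R = Rmax * C / (K + C)`: `K` is profiled on a log grid spanning four
decades beyond the measured concentrations (with `Rmax` given in closed
form conditional on `K`), refined by bounded search and polished by
Gauss-Newton, making the noiseless round trip exact to ~1e-9 relative.
Fits with `r^2 <= 0.91` are flagged, not rejected.  Two replicate-handling
schemes are implemented — fit each replicate and average the constants
(mean and SE across replicates), or average the seven concentration-response
points (with SE) and fit once — and agree on synthetic data.  Affinities
are compared with Welch's two-tailed t test on -log10-transformed constants
(Satterthwaite df); two zero-variance groups with equal means give p = 1 by
convention.

**Generator.**  `simulate_kinetics` produces 1:1 Langmuir traces:
association `R(t) = Rmax*C/(C+Kd)*(1 - exp(-(kon*C + koff) t)) + drift*t +
noise`, dissociation `R_end * exp(-koff t) + noise` (drift enters the
association phase only), plus a per-replicate blank of drift + noise.
Defaults — `Kd = 3e-8 M`, `kon = 5e5 /(M s)` (hence `koff = 0.015 /s`),
`Rmax = 1 nm`, seven log-spaced concentrations over 1 nM-100 uM, 2% noise,
3 replicates, 600 s phases sampled at 1 s — were chosen once so the
association saturates inside the sampled window (the last-500-sample rule
then sits on the plateau: the residual rise contributes < 1% bias) while
traces stay small.  A real instrument samples far faster and for longer;
the last-500-samples rule operates on whatever grid is present.  One
limitation is intrinsic: under ideal 1:1 kinetics the initial rate is
`Req * kobs = Rmax * kon * C`, *linear* in concentration, so the
half-maximal initial-rate constant (Km) is only weakly identified on
synthetic traces; Km is meaningful on real traces, where instrument
saturation bends the initial-rate curve.  The recovery tests therefore
exercise Kd.

## Synthetic data scales

The default synthetic domain-family fixture is 5 groups x 10 taxa, 95
residues, on one shared tree with group stems of 0.8 and within-group
root-to-tip depth 0.5 substitutions/site — the scale of a deep
five-subfamily domain phylogeny, without claiming any real dataset's
values.  Simulation experiments in the tests use 8-12 taxon trees, 60-200
sites, and 20-50 replicates; these sizes were chosen as the package's
desk-scale defaults, with replicate counts configurable upward.  What
passing tests show is internal correctness and calibration *under the
generating models*; they cannot show robustness to alignment error,
among-site compositional heterogeneity, or non-stationary evolution, none
of which the generators emulate.

## Numerical choices

- Per-node likelihood rescaling by the per-site maximum; log-scalers
  accumulate per site.
- MAP and second-best calls break posterior ties by the fixed residue
  order; NJ pair selection breaks Q-matrix ties toward the first pair in
  row order; Fitch ambiguity resolves toward presence.
- The LRT statistic is clamped at zero; SH-test ties count toward
  non-rejection.
- All stochastic stages take explicit seeds and are bit-reproducible;
  experiment replicates draw child seeds below 2^31 from one generator.
- Degenerate inputs raise: empty FASTA, duplicate ids, stop codons in
  frame, negative weights, non-monotone trace time, all-gap HMM input,
  flat concentration-response curves.
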
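# Methods

## The question and the model

Some genes carry two intein insertion sites close together; in haloarchaeal
*mcm* these are the heavily invaded sites a and d. When both inteins are
present, do they ever invade an empty allele *together* ("co-homing", one
gene-conversion event copying both), or only one at a time? The
phylogenetic version of this question is a model-comparison problem on the
joint occupancy of the two sites.

Occupancy is coded as one of four states — `--`, `-D`, `A-`, `AD` — and
evolves along a rooted phylogeny as a continuous-time Markov chain with
instantaneous rate matrix Q (an Mk-type model). Two nested, all-rates-
different parameterizations are compared:

* **no_cohoming** (k = 8): only single-site gains and losses,
  `-- ↔ -D`, `-- ↔ A-`, `-D ↔ AD`, `A- ↔ AD`, each direction its own rate.
* **cohoming** (k = 10): the same eight plus the direct double transitions
  `-- ↔ AD`, the signature of co-homing (and simultaneous double loss).

Rates are in expected transitions per unit branch length, so their scale is
tied to the branch-length units of the input tree; no separate calibration
is applied. Disallowed cells of Q are exactly zero and each diagonal entry
is minus its row sum.

The likelihood of the tip states is computed with Felsenstein's pruning
algorithm (post-order propagation of partial likelihoods through
P(t) = exp(Qt)), with per-node rescaling for numerical stability and no
restriction to bifurcating trees — polytomies are handled natively.
Transition matrices for all branches are obtained from one
eigendecomposition of Q per likelihood evaluation
(P(t) = V e^{Λt} V⁻¹, applied to all branch lengths in one batch); when the
eigenvector matrix is ill-conditioned (condition number ≥ 1e8, e.g. equal
rates giving repeated eigenvalues), the implementation falls back to
scaling-and-squaring (`scipy.linalg.expm`) per branch. The two routes agree
to 1e-10 in the test suite.

Models are compared by the small-sample corrected Akaike information
criterion, AICc = −2 lnL + 2k + 2k(k+1)/(n−k−1) with **n = number of
taxa**, and by the relative likelihood exp((AICc_min − AICc_i)/2).

### Root prior

The probability at the root must be summed against a prior over the four
states. The default is flat (¼ each); an equilibrium-of-Q prior or a user
vector can be selected, and the choice is recorded in every fit result and
report. A flat prior has one consequence worth knowing: on data with zero
variation (every taxon in the same state) the maximized likelihood is not
the prior mass of that state but approaches 1, because unbounded loss rates
funnel every root state into the observed one. The pipeline flags
zero-variation inputs explicitly.

### Optimization

Rates are maximized in log space with L-BFGS-B inside bounds
[1e-9, 1e5] — the wide upper bound mirrors raising the likelihood-search
ceiling to 100,000 so genuinely fast transitions are not silently
truncated. Multi-start strategy: the first (up to) three starts are
deterministic, at rates of 1, 10 and 0.1 expected events per mean
root-to-tip path; remaining restarts are drawn log-uniformly from a
configurable window (default [1e-3, 1e2] times the 1-event scale) with a
fixed seed. We deliberately do not draw starts log-uniformly over the full
14-decade bound range: almost all such starts land on flat plateaus
(saturated or frozen chains) where gradient ascent stalls, and the
deterministic multi-scale starts bracket every regime the data can
identify. All restart optima are reported so flat-likelihood pathologies
remain visible; a fit in which no restart converges is flagged, never
silently returned.

When both models are fitted together (`fit_models`, the `compare` command),
the supermodel's start list additionally includes the nested model's
optimum with the two co-homing rates at the lower bound. This guarantees
the nesting inequality lnL(cohoming) ≥ lnL(no_cohoming) up to optimizer
tolerance and costs one extra local search.

## MAD rooting

Unrooted input trees are rooted by minimal ancestor deviation. For a
candidate root position and a tip pair (i, j), the induced ancestor is the
point a on the i–j path nearest the root, and its relative deviation from
the pair midpoint is r_ij = |2·d(a,i)/d(i,j) − 1|. On each branch the
position minimizing the sum of squared deviations of root-spanning pairs
has a closed form (a weighted least-squares projection, clamped to the
branch); pairs on one side of the branch contribute position-independent
deviations. The branch/position with the smallest root-mean-square
deviation wins. Exact ties are resolved toward the first branch in a
deterministic post-order traversal and logged. Tip pairs at zero patristic
distance are excluded (logged); trees with all-zero branch lengths are
rejected as degenerate. Zero-length branches are legal candidate locations
whose positions collapse to a point. The closed form is verified against a
dense grid search (1e-4 step) in the tests.

## Occupancy statistics

The taxon-by-site table records presence/absence at all four sites (a–d).
Mini-inteins (no detectable homing endonuclease) count as present; the
full/mini distinction travels in separate optional columns. The expected
pattern distribution under independent invasion uses the product-binomial
form E_p = N·Π_s f_s^{p_s}(1−f_s)^{1−p_s} with f_s the observed marginal
frequency; expected counts are kept as reals. No significance test is
attached by default — the comparison is descriptive — but an exploratory
chi-square (df = 16 − 1 − 4) is available and carries the usual small-cell
caveats. The Markov models see only sites a and d; the projection
`to_ctmc_states` discards b and c by design.

## Insertion-site flanks

Insertion points are between-residue coordinates: the intein block occupies
alignment columns [start, end), the −1 residue is the last ungapped residue
before start, +1 the first at/after end. A sequence counts as invaded when
at least 50% of its block columns are ungapped (configurable), which
tolerates ragged block boundaries. Flank windows collect up to w = 20
ungapped **residues** per side — "twenty residues" is read as residues, not
alignment columns, since gap-riddled rows would otherwise contribute
near-empty windows. Sequences with fewer than w available residues are
included at reduced coverage. Per-column information content is
log2(20) − H − e_n with the standard small-sample correction
e_n = 19/(2·ln2·n), clamped to [0, log2 20].

## PSSM scanning

PSSMs are built from block alignments with mass-proportional pseudocounts,
s(p, aa) = log2((c+αb)/((n_p+α)b)), α = 1 and uniform background 1/20 by
default (both configurable and recorded in the PSSM metadata); gapped rows
contribute only to the columns they cover. Ambiguity codes score 0.
Window hits at or above threshold — default 60% of the consensus
(maximum-attainable) score, since no published threshold exists — are
merged per-PSSM to the best-scoring offset, then merged across PSSMs into
intein regions when within 150 residues of each other (inteins are large;
the splicing-region motifs of one intein sit well inside that span).
Regions are classified *full* when any of the four LAGLIDADG HEN-block
PSSMs fires inside the region (±50 residues margin), otherwise *mini*.
All scores are emitted, so thresholds can be re-applied post hoc. Group
summaries use intein counts as percentage denominators and report NaN for
empty groups.

## Synthetic data: what it emulates and what it does not

The generators produce every input with known ground truth:

* **Trees**: Yule or birth–death processes conditioned on the tip count
  (dendropy's simulator), stopped at the n-th lineage and extended by the
  exponential waiting time of the n-lineage epoch, so trees are strictly
  ultrametric with no coincident tips and the expected Yule crown depth is
  Σ_{k=2..n} 1/(kλ). Branch lengths are in time units.
* **Trait histories**: exact Gillespie simulation of the occupancy chain
  along each branch; every event is recorded, and replaying the event list
  reproduces the tip states exactly (a tested invariant).
* **Alignments**: an i.i.d. extein scaffold with a haloarchaea-like
  (acidic-rich) residue composition, intein blocks for invaded rows,
  all-gap blocks otherwise, and configurable junction-residue rules —
  defaults emulate a conserved site a (+1 always S) and a dichotomous
  site d (+1 S when invaded, P with probability 0.9 otherwise).
* **Proteomes**: random host proteins with planted inteins built from
  fixed random consensus motifs (two splicing-region motifs, four HEN
  blocks for full inteins); the scanner's PSSMs are built from mutated
  copies of the same motifs, as in real use where PSSMs come from known
  intein alignments.

Not emulated: sequence evolution along the tree (sites are exchangeable
noise, not phylogenetically correlated), intein sequence divergence
families, alignment error, and compositional heterogeneity among lineages.
Passing tests therefore demonstrate correctness of the algorithms under
the stated models, not robustness to real-alignment artifacts.

Default study conditions used by the recovery and selection experiments:
gain/loss rates drawn uniformly from [0.5, 2.0] events per unit branch
length; 1000-tip trees for rate recovery (10 replicates, median relative
error per rate < 50%); 500-tip trees for AICc model-selection consistency
(correct preference in ≥ 8/10 replicates); 80-tip trees for the nesting
check; 20-tip ultrametric trees for MAD root recovery (50 replicates).
The experiments use 5 optimizer restarts for rate recovery (the 8-rate
surface occasionally has a competing local basin that 3 starts miss), 3
for model selection, and 2 for the nesting check where the warm start does
the work.
These sizes give each experiment enough signal for its assertion while the
whole suite completes in a few minutes.

One global seed expands into independent substreams (SeedSequence spawning)
for tree, history and sequence components, and every generated artifact
embeds its seed.

## Known limitations

* The two transition models assume time-homogeneous rates along the whole
  tree and complete, unambiguous tip states; missing data are rejected
  rather than marginalized.
* AICc uses the number of taxa as the sample size; taxa are not
  phylogenetically independent samples, so the correction is a convention,
  not an exact small-sample theory.
* With 8–10 free rates and four states, some rates are weakly identified
  on small trees; the per-restart log-likelihood report is the intended
  diagnostic.
* PSSM scanning assumes motif-bearing inteins similar to the blocks the
  matrices were built from; deeply divergent or permuted inteins are
  outside its reach.
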
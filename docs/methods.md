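# Methods

`dyngrn` reconstructs stage-specific gene regulatory networks during a
differentiation time course by combining four kinds of data: per-stage
expression (RNA-seq FPKM), per-stage histone-modification and RNA-polymerase
ChIP signal, transcription-factor ChIP peaks for a training panel of TFs,
and TF perturbation outcomes.  The method has two steps: a per-base binding
classifier, and a time-varying dynamic Bayesian network (DBN) over
cis-segment weights.

## Step 1 — per-base binding probability (LR score)

Candidate sites are PWM hits: windows whose min–max-normalized log-odds
score reaches the scan threshold (default 0.90) on either strand of a
gene's cis-region (a 40 kb window centered on the TSS by default; bases in
overlapping windows belong to the gene with the nearest TSS, ties to the
smaller TSS coordinate).  A hit overlapping a ChIP peak of its own TF is a
positive example, otherwise negative.  Each hit center carries 69 features:

* 15 context-independent sequence features — conservation scores for two
  alignments with explicit availability indicators, CpG-island membership,
  `ln(d + 5)` distance to the nearest TSS, repeat membership, five
  gene-structure indicators, and GC fraction in a 101-nt window;
* 4 expression features of the owning gene — `ln(FPKM + 1)` at stages t and
  t+1 and mutually exclusive up-/down-regulation indicators (a fold-change
  caller with ratio ≥ 2 on FPKM+1 and |ΔFPKM| ≥ 1 is provided; calls can
  also be supplied);
* 50 signal features — for each of H3K27ac, H3K4me1, H3K4me3, H3K27me3 and
  RNAP, the mean asinh-transformed binned intensity in centered windows of
  total width 1000/500/100/50/10 nt at stage t, plus each window's change
  from t to t+1.  Windows are clipped at the cis-region boundary and
  averaged over the overlapping 10-bp bins, unweighted.

Columns are standardized (sample sd); the training scaler is reused at
prediction time.  The classifier is plain logistic regression fitted by
IRLS/Newton to a gradient norm below 1e-8 (≤ 100 iterations).  Saturated
fitted log-odds (|η| > 30) flag probable perfect separation; the last
iterate is kept with a warning.  An elastic-net refit (λ by seeded 3-fold
deviance CV; mixing defaults to pure L1) is available as a robustness
check.  Generalization is measured by leave-one-TF-out cross-validation:
the model never sees the held-out TF's rows (standardization refitted per
fold), and performance is the AUC over that TF's hits.  The fitted model
scores every base of every cis-region at every stage transition — the LR
score.

## Step 2 — time-varying DBN

Expression dynamics are modeled as `X^{t+1} = A^t X^t + ε` on the
`log(FPKM+1)` scale.  Row i of `A^t` factors as `(u^{i,t})^T B^{i,t}`:
`u^{i,t}` weights the gene's 50-bp cis-segments (5-bp step, so adjacent
segments share 45 bp), and the binding-potential matrix has
`B_{k,j} = (mean LR over segment k) · π_{ij}` when TF j has a resolved PWM
hit in segment k, else 0.  `π_{ij}` is 1 when the perturbation matrix
supports the j→i relation and 0.25 otherwise.  Only abundantly expressed
TFs (FPKM > 25 at stage t) with a known PWM enter as regulators.  Binding
potentials below 1e-4 are treated as no binding: an occupancy probability
that small carries no evidence and would only produce wildly
ill-conditioned weights.

Per gene the weights solve the convex program

    min Σ_t (x_i^{t+1} − (u^{i,t})^T B^{i,t} X^t)²
        + λ1 Σ_t ‖u^{i,t}‖₁
        + λ2 Σ_t ‖(u^{i,t})^T B^{i,t} − (u^{i,t+1})^T B^{i,t+1}‖₁

The data term defaults to the squared residual (consistent with reporting
variance explained); an absolute-loss variant is available.  The printed
form of the model multiplies `B^{i,t}` by the full expression vector
`X^t` — the only reading under which the shapes conform.  Weights are
unconstrained in sign; "positive edges" are entries of `A^t` above 1e-8
(the solver's noise floor).

### Solver

Segments with an all-zero binding row are provably zero at any optimum and
are dropped before solving.  Pure-lasso subproblems (λ2 = 0) go through a
ladder of LARS homotopy, compiled coordinate descent and a plain Python
coordinate descent, each candidate validated by an exact Fenchel duality
gap (the dual multiplier for the zero rows is refined by a small
∞-norm-minimizing LP when the least-squares candidate overshoots the unit
box).  General fused systems use ADMM on the row-normalized splitting with
column (variable) scaling, best-objective tracking, active-set polishing
(an equality-constrained QP on candidate active sets), and the same
duality-gap certificate; as a last resort several penalty parameters ρ are
tried and agreement of two independent runs to 1e-6 relative is accepted.
Final per-gene solves certify at relative gap 1e-6; cross-validation
sub-solves certify at 1e-4, where objective differences cannot affect the
selection.  The solver was checked against an independent epigraph-QP
solve (SLSQP) on randomized instances.

### Hyperparameters

(λ1, λ2) are chosen by leave-one-transition-out CV: the weights are
refitted without one transition (the smoothing term restricted to adjacent
fitted pairs) and the held-out transition is predicted with the temporally
nearest fitted weight vector (ties to the earlier one).  Because each gene
contributes one scalar equation per transition, the fits interpolate, and
the plain arg-min of the CV error systematically favors vanishing
penalties — shrinkage can only add prediction bias in an interpolating
regime.  The default selection therefore applies the one-standard-error
rule: among grid points within one SE (over genes) of the minimum, the
sparsest pair wins.  The plain arg-min (`rule="min"`) remains available.

### Significance and perturbation

Segment-weight significance uses a bootstrap: per replicate the per-base
LR scores of the cis-region are resampled with replacement (each
transition's track independently; block resampling of segment means is
available), B is rebuilt and the gene re-solved at the point estimate's
hyperparameters.  With N replicates, `p = (#{uₙ > u} + 1)/(N + 1)`,
bounded below by exactly 1/(N+1).  A replicate whose solve fails twice is
conservatively counted as an exceedance.

In-silico induction multiplies one TF's FPKM by a fold (default 5),
re-logs it, and propagates the change through `A^t`; genes move up or down
by the sign of the predicted change (|Δ| ≤ 1e-8 is unchanged).  Agreement
with experimental perturbation calls is a two-sided Fisher's exact test on
the 2×2 up/down table, with unchanged genes excluded.

## Synthetic data

The generator emulates every input at toy scale, writing the same formats
the readers accept.  A toy chromosome tiles adjacent gene loci (TSS at
each locus center) with exon/CDS structure, conservation (baseline
U(0, 0.3) with 85% availability), CpG islands at promoters and scattered
repeats.  Motif instances of an informative PWM panel are planted in
jittered, well-separated slots; truly bound instances receive a ChIP-like
peak, elevated conservation over the footprint, and an enhancer-like
signal: a plateau bump (flat ±520 nt, linear taper to ±820 nt) on
H3K27ac/H3K4me1 minus a Gaussian dip (sd 30 nt) at the site center, plus
promoter-like H3K4me3/RNAP bumps at TSSs and Poisson noise.  Bump
amplitudes are modulated per site *and* per stage (U(0.6, 1.4) around the
base amplitude): if all sites moved in lockstep between stages, the
signal-change features would encode the stage rather than the site, and a
classifier trained on some transitions would collapse on the others —
per-site modulation is what real stage-specific binding looks like.  The
plateau width is chosen so that, without a dip, the 100-bp and 1-kb window
means coincide at the site center.

For network inference the first genes are TF genes holding their own
motif, self-regulating geometrically (factors 0.97/1.03/0.95/1.02/0.99
from initial FPKM 60/45/80/50/100, so every TF stays above the FPKM > 25
threshold at all four stages).  A designed sparse edge set — a hub TF with
seven up- and seven down-regulated targets (down-targets compensated by a
second TF so expression stays positive), plus a few single-regulator
edges — is realized exactly: each edge is mediated by one planted bound
instance, the ground-truth LR track is 0.02 baseline/0.8 at bound
footprints, the perturbation matrix P is derived from the designed network
by simulated 5-fold induction (threshold 0.2 on the log scale), and
`u*` is set so `(u*)^T B*` reproduces the designed `A*` to machine
precision.  Bound decoy instances without regulatory weight are planted as
well, so inference must reject spurious candidate regulators.  Expression
follows `X^{t+1} = A* X^t + ε` with σ = 0.05 by default over T = 4 stages.
All generators are pure functions of their seed.

A separate, larger dataset (100 genes × 3 kb, 20 instances per gene, 60%
bound) trains and evaluates the binding classifier; its TF panel is split
between the first and the last stage transition, mirroring a panel
profiled in two different cell types.  For bootstrap calibration a null
gene is generated whose LR scores are i.i.d. uniform over a region much
wider than one segment: the central segment's bootstrap p-value is then
(discretely) uniform, because the segment mean and its resamples are draws
from the same distribution.  A single-segment null would *not* be
calibrated — the bootstrap recentres on the observed segment mean — which
is why the null region is 500 nt.

### What the synthetic data does not emulate

Mappability artifacts, fragment-length effects, nucleosome positioning,
copy-number or GC biases, TF cooperativity/competition at shared sites,
indirect (tethered) binding, and realistic motif degeneracy (planted
instances are exact consensus).  Classifier AUCs near 0.99 and variance
explained near 100% on this data therefore say the implementation is
correct, not that real-data performance would be that high.

## Numerical choices and limitations

* Coordinates are 0-based half-open throughout; signal re-binning is a
  coverage-weighted mean with gaps as 0; PFM pseudocount 0.01 per cell.
* Even-length motif centers use the left-of-center base; overlap-resolution
  ties keep the 5'-most hit; resolution is per (gene, TF) by default so
  co-located motifs of different TFs can coexist.
* `N` bases score the column-minimum log-odds.
* The rank-sum comparison of enhancer vs random scores is exact for both
  samples ≤ 10, else the tie-corrected normal approximation; all-tied
  samples report p = 1.
* TF enrichment in high-LR regions uses a one-sided binomial test against
  the genome-wide high-LR base fraction, minimum p over a TF's PWMs,
  Benjamini–Hochberg across TFs.
* Negative regulatory edges are hard to recover through the inference path:
  with one scalar equation per transition a single compensating TF can
  absorb a dropped negative edge, so at 1-SE-selected penalties the
  negative hub edges are regularized away while positive-edge recovery
  stays high.  Perturbation-direction validation therefore uses the ground
  truth network in the self-consistency test.
* Problem sizes in the shipped tests (20-gene networks, 2 kb regions,
  ~2,000 classifier rows, 200 bootstrap null genes at N = 100) were chosen
  to exercise every code path at desk scale.
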
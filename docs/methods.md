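# Methods

`cdloop` calls chromatin loops from a single-chromosome Hi-C contact map in
three stages: a pre-trained window classifier produces a per-pixel prior, a
prior-conditioned classification diffusion model refines that prior into a
probability score with an uncertainty summary, and density-peaks clustering
reduces the score field to a sparse set of representative loop calls.  This
note records the model, the parameter choices, the synthetic data regime the
package is validated on, and the known limitations.

## Contact maps and preprocessing

A chromosome is binned at a fixed resolution (default 5 kb); the contact
matrix `M` is symmetric with non-negative counts.  Coverage bias is removed
by Knight–Ruiz-style matrix balancing: a positive diagonal `D` is found by
symmetric fixed-point iteration so that every unmasked row sum of `D·M·D` is
equal (relative residual below `tol`, default 1e-6).  Bins with zero marginal
are masked out of the balancing.  The balanced layer is rescaled to preserve
the total count mass: this keeps balanced entries on the count scale, so the
interaction-frequency prefilter (`min_if = 1`, see below) retains its
meaning.  Model windows are taken from the balanced layer by default
(balancing is a correction applied before any learning); the layer is a
config knob.

The model input for a bin pair `(i, j)` is the `2w x 2w` window (w = 14, so
28 x 28) with rows `i-13 .. i+14` and columns `j-13 .. j+14`; the centre
pixel sits at window index (13, 13).  Windows are `log1p`-transformed before
entering either network; raw Hi-C counts are heavy-tailed and the
compression stabilises optimisation.  Candidate pairs whose window would
cross the chromosome boundary are skipped.

Sequencing-depth reduction is emulated by binomial thinning: each count in
the upper triangle is replaced by a Binomial(count, fraction) draw and
mirrored, equivalent to retaining each read pair independently.

## Training samples

Positive pixels come from interaction labels in BEDPE form.  Two label
files can be supplied and are merged (mirroring a CTCF ChIA-PET set plus an
H3K27ac HiChIP set, which together cover long- and short-range loops).
Pairs with anchor-midpoint separation outside 30 kb – 3 Mb are discarded; an
anchor spanning k bins contributes k bin rows/columns, so a label covering
several pixels yields one positive per pixel, deduplicated.

Negatives are drawn three ways, all rejected if they coincide with a
positive: (1) per positive, two random pairs at the same bin distance;
(2) pairs at distances resampled with replacement from the positive distance
multiset, as many as there are positives; (3) pairs at distances strictly
greater than the largest positive distance (capped by the chromosome span),
again as many as there are positives — roughly 4 negatives per positive
before filtering.  Negative windows that are entirely zero are dropped;
positives are kept regardless.  Positives are augmented by horizontal,
vertical and double flips (4 variants including identity; a 3-variant mode
is available); negatives are not augmented.

## Prior network

The prior `f(x)` is a LeNet5-style classifier: two blocks of
(5 x 5 convolution → batch norm → ReLU → 2 x 2 average pooling) with 6 and
16 feature maps (the first convolution pads by 2, giving the classic
28 → 14 → 5 spatial ladder), then dense layers 400 → 120 → 84 → 2 with ReLU
between them.  Training minimises cross-entropy with Adam (lr 1e-3, batch
128); the parameters with the best validation accuracy (training accuracy
when no validation split is given) are returned.  The softmax output is the
two-class prior probability vector used everywhere downstream.

## Classification diffusion

Labels are one-hot vectors `y0` in R^2.  The forward process interpolates
the label toward the prior instead of toward zero:

    q(y_t | y0, f) = N( sqrt(abar_t) y0 + (1 - sqrt(abar_t)) f, (1 - abar_t) I )

with `alpha_t = 1 - beta_t`, `abar_t = prod alpha_s`, so the endpoint is
`N(f, I)`.  The reverse posterior has variance
`btilde_t = (1 - abar_{t-1}) / (1 - abar_t) * beta_t` and mean

    mu = gamma0 y0 + gamma1 y_t + gamma2 f
    gamma0 = beta_t sqrt(abar_{t-1}) / (1 - abar_t)
    gamma1 = (1 - abar_{t-1}) sqrt(alpha_t) / (1 - abar_t)
    gamma2 = 1 + (sqrt(abar_t) - 1)(sqrt(alpha_t) + sqrt(abar_{t-1})) / (1 - abar_t)

with `gamma0 + gamma1 + gamma2 = 1` identically; setting `f = 0` recovers the
standard DDPM formulas, which the tests verify against independently written
closed forms.  The convention `abar_0 = 1` makes `btilde_1 = 0`, so the last
reverse step is deterministic and returns exactly the final `y0` estimate.

The noise predictor takes (window, y_t, f, t).  The flattened window passes
through three dense layers to a `width`-dimensional embedding; the
concatenation `y_t ⊕ f` passes through a dense layer and is
Hadamard-multiplied by a learned projection of a sinusoidal timestep
embedding; the two branches fuse by Hadamard product; two further
`width`-wide dense layers follow, each preceded by a timestep-embedding
Hadamard product; batch norm and Softplus follow every hidden dense layer.
The published architecture uses width 2048; the desk default is 128, which
is ample for the synthetic task and keeps a full run on one CPU in minutes.
The image branch is timestep-independent, so at inference it is computed
once per window and only the small response head runs per reverse step.

Training uses the simplified ELBO surrogate: per batch, `t ~ U{1..T}`,
`eps ~ N(0, I)`, `y_t` from the closed-form forward kernel with the frozen
prior, minimising the MSE between `eps` and the network output (Adam,
lr 1e-3, batch 128).  The schedule is linear in beta from 1e-4 to 0.02;
T = 1000 is the conventional full-scale setting and T = 100 the desk
default.

Scoring a candidate runs the reverse chain from `y_T ~ N(f, I)` down to
t = 1, estimating `y0_hat = (y_t - (1 - sqrt(abar_t)) f - sqrt(1-abar_t)
eps_hat) / sqrt(abar_t)` at each step and sampling the posterior.  The final
estimate maps to a score by softmax; the positive-class component, averaged
over `n_draws` independent chains (default 10), is the loop score `s(i, j)`.
The spread of the draws gives a normal-approximation 95% CI and a two-tailed
one-sample t-test against 0.5.  With a single draw the CI and p-value are
reported as NaN.  The repeated-draw construction of the CI/t-test is this
package's interpretation; only the score itself feeds the caller.

## Candidate generation and clustering

Genome-wide prediction enumerates pairs `i < j` with separation inside
30 kb – 3 Mb whose contact value is at least `min_if = 1` and whose 28 x 28
window (computed with a summed-area table) has fewer than 200 zero entries —
thresholds taken over from the published prefilters, all exposed as flags.
After scoring, pairs with score strictly greater than 0.5 survive.  A
candidate with fewer than 15 candidates (itself included) in the 5 x 5
Chebyshev square around it is an isolated prediction and is removed; removal
is a single simultaneous pass, deliberately not iterated.  Local density
`rho` is the number of surviving candidates within Chebyshev radius 2;
`delta` is the Chebyshev distance to the nearest candidate with strictly
higher density, computed by expanding-radius K-D-tree queries, with ties in
`rho` broken by score and then by index so the order is total; the global
maximum receives `max(other deltas) + 1`.  Candidates with `delta >= 5` are
the final loops.  The 15-of-25 occupancy rule is strict (a 5 x 5 square has
only 25 cells); both numbers are flags for users who prefer a radius-5
(11 x 11) reading.

## Synthetic data regime

The generator plants loops in a distance-decay background:
`mu[i,j] = A (|i-j|+1)^(-g)` times, per loop at `(a, b)`,
`1 + (amp - 1) exp(-cheb((i,j),(a,b))^2 / (2 width^2))`, times an optional
TAD-block factor; counts are Poisson draws, symmetrised.  Enrichment is
multiplicative so balancing cannot erase it.  Desk defaults: 1200 bins at
5 kb, A = 20, g = 1, 60 loops of amplitude 8 and width 2.5 bins at
separations of 8–13 bins (40–65 kb), placed at least 12 bins apart.  Labels
are emitted as two independent BEDPE files (emulating the two assay types),
each jittering anchors to spans of 1–3 bins around the true pixel, which
exercises multi-pixel positive splitting and teaches the classifier the
blob-like neighbourhood of a dot, as multi-bin assay anchors do on real
data.

This regime emulates a low-depth map: adjacent-bin counts around A/2 and
mostly-zero pixels beyond ~15 bins, which is where the 200-zero-element
prefilter becomes informative and confines candidates to short range —
keeping the full train-and-call cycle around 4 minutes on one CPU.  What it
does not model: overdispersion beyond Poisson, A/B compartments, realistic
TAD nesting, coverage bias along the chromosome, trans contacts, and loops
at the long-range end of the band.  Passing the recovery test therefore
shows the machinery is wired correctly and separates planted signal from
decay background; it does not certify performance on real Hi-C.

Recovery varies noticeably with the simulation seed (F1 between roughly 0.2
and 0.9 over a handful of seeds, typically around 0.7).  The variance is not
a training instability — prior accuracy and the diffusion loss are stable
across seeds — but a consequence of the isolation rule being a hard cliff:
ambiguous off-centre pixels score near the 0.5 cutoff, so a small shift in
the learned decision boundary moves whole 5 x 5 blobs across the 15-of-25
occupancy threshold.  Precision stays near 1 throughout; recall is what
fluctuates.  Users who want smoother behaviour can lower `--min-neighbors`
or widen `--square`, at the cost of departing from the published constants.

Evaluation matches predictions to truth one-to-one, greedily in score
order, with both anchor midpoints within a tolerance (inclusive); F1 at
±1 bin is the headline number, and a score-shuffled null caller (scores
permuted across candidates before clustering) provides the floor any real
signal must beat.  APA averages the 21 x 21 pileup over the top-scoring
loops and divides the centre by the mean of the 6 x 6 lower-left corner; it
is only meaningful for loops whose flank window stays off the diagonal, so
the APA sanity check plants loops at 150–400 kb.

## Numerical and design notes

- All randomness flows from one seed, fanned out to stages by fixed
  offsets; reruns of any stage are bit-identical.
- Networks run in float32; schedule algebra and score summaries in float64.
- Batch norm uses batch statistics in training and running statistics at
  inference, so inference is deterministic.
- KR balancing raises (naming iteration count and residual) rather than
  returning an unconverged layer.
- `.cool` input is read directly via HDF5 (single-resolution layout);
  3-column sparse text and dense text are the portable interchange formats,
  and BEDPE round-trips losslessly.
- Degenerate cases: empty candidate set is legal everywhere downstream;
  a single candidate gets delta 1; an APA corner mean of zero yields NaN
  rather than a crash; trans-chromosomal label pairs are read but ignored
  by intra-chromosomal operations.
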
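# Methods

`oculodx` implements a three-class eye-movement classifier for
oculomotor-disorder screening: healthy controls (C1), brain-injury
patients (C2) and vertigo patients (C3). A subject watches a moving light
spot under `s = 2` stimulus schemes while an infrared camera records 250
frames at 30 fps; from every frame `k = 3` pupil parameters (abscissa
*x*, ordinate *y*, area *r*) are measured. The pipeline then stacks three
learning stages: per-feature LSTM classifiers, C4.5 decision trees on the
LSTM output probabilities, and a randomized forest of such trees.

## Pipeline model

**Original features.** Each per-frame parameter series `f = [f_1..f_M]`
(`M = 250` frames) is min-max normalized,

    g_i = (f_i − min f) / (max f − min f),

so `g ∈ [0, 1]^M` with its minimum at exactly 0 and maximum at exactly 1.
A constant series, where the formula is 0/0, maps to all zeros — a
constant carries no information, and zeros keep the range valid. With two
schemes and three parameters every subject yields `s × k = 6` original
features, ordered scheme-major (sweep-x, sweep-y, sweep-area, zigzag-x,
zigzag-y, zigzag-area). This canonical order is fixed so classifier *i*
downstream always consumes the same feature.

**Evolutionary features.** Each original feature is cut into `t = 10`
time slices of 25 samples; the slices are the timestep inputs of an LSTM
with 64 hidden units whose final hidden state feeds a fully connected
layer and a 3-way softmax `(P1, P2, P3)`. One classifier is trained per
feature on subject group 1 (full-batch Adam, learning rate 1e-3,
cross-entropy, stopping at training accuracy 1.0 or 200 epochs). Since
`P1 + P2 + P3 = 1`, only `(P1, P2)` are kept; stacking the pairs over the
6 classifiers gives the 12-vector `Ef = [f_1..f_12]` with classifier *i*
contributing `f_{2i−1} = P1` and `f_{2i} = P2`.

The network is implemented directly in numpy (forward pass,
backpropagation through time, Adam). At this scale — 32 training
sequences of 10×25 — a full training run takes a fraction of a second and
is bit-reproducible from its seed, which the stacked design needs: the
forest stage must see identical evolutionary features on every rerun.

**C4.5 on segmentation points.** With `N = 32` group-2 subjects and
`M_feat = 12` evolutionary features, each feature offers `N − 1 = 31`
thresholds (midpoints between consecutive order statistics), a nominal
pool of `12 × 31 = 372` segmentation points. Node branching maximizes the
information gain rate `gr(D, J) = [H(D) − H(D|J)] / H(J)` where `H` is
Shannon entropy in bits and `H(J)` the two-way split entropy. Trees grow
unpruned to purity; a node becomes a leaf when pure, when its feature
vectors are identical, or when no usable candidate remains.

**Random forest.** Each of the 20 trees is grown on a bootstrap resample
(32 draws with replacement). At every node `floor(log2(372)) = 8` points
are drawn uniformly without replacement from the tree's pool of unused
points; the winner is *marked* and never reused within that tree (the
mark set is shared across the whole tree, not across trees — forest-wide
marking would exhaust the 372-point pool after a few dozen nodes).
Prediction is a majority vote, ties to the lowest class index.
Out-of-bag (OOB) evaluation judges each training sample only by the trees
whose bootstrap missed it; samples in every bootstrap are excluded and
reported.

**Evaluation.** Accuracy, one-vs-rest precision/recall/F-score, ROC and
AUC (trapezoid rule). Single trees emit hard labels, so their one-vs-rest
ROC curves consist of exactly two line segments; the forest is scored by
its per-class vote fraction, which yields a finer curve. Macro averaging
interpolates per-class curves on the union FPR grid; micro averaging
pools all (score, indicator) pairs.

## Synthetic cohort

No public corpus of labeled clinical eye-tracking recordings accompanies
this problem, so the package ships a cohort simulator that is itself
first-class, tested code. Its defaults define the study conditions: 96
subjects in three disjoint groups of 32, each group containing 12 C1, 8
C2 and 12 C3 subjects; group 1 trains the LSTMs, group 2 the trees and
forest, group 3 is the test set.

**Stimuli.** Screen coordinates are normalized to [0, 1]². The
*horizontal sweep* (optokinetic test) moves the target left to right
along the midline with a 100-frame sawtooth period. The *zigzag* (smooth
pursuit test) sweeps rightward once over the 250 frames while the
ordinate zigzags between 0.25 and 0.75 with 5 teeth.

**Gaze model.** Gaze is the stimulus delayed by a latency, scaled about
the screen center by a tracking gain, plus Gaussian noise. Class
signatures: C2 (brain injury) has reduced gain 0.85, latency 6 frames,
noise sd 0.02 and Poisson saccadic jumps (rate 0.04/frame, amplitude sd
0.08, offsets decaying ×0.8/frame as gaze re-acquires the target);
C3 (vertigo) has nystagmus — a 3 Hz, 0.05-amplitude sawtooth (slow drift,
fast reset) applied horizontally with a 0.35× vertical component, since
vestibular nystagmus is rarely purely horizontal — plus pupil-area jitter
of 40 px²; C1 is gain 1.0, latency 2, noise sd 0.01. Pupil area is the
model mean (1200 px²) attenuated by `1 − 0.3·ē²` where `ē²` is the mean
squared normalized gaze eccentricity: the camera sees the pupil
foreshortened as the eye rotates, which couples the area channel to the
same oculomotor signature as the position channels.

These parameters are stand-ins chosen to be plainly distinguishable yet
overlapping; they are **not** claims about the diseases. Consequently the
pipeline's high accuracy on the synthetic cohort demonstrates that the
stacked method recovers class structure that is present — not that the
method reaches any particular accuracy on clinical data. The simulator
also omits blinks, the pupillary light reflex, head motion and
calibration error; the pupil-module tests therefore use noiseless
rendered ellipses as segmentation ground truth, and the trace-level
pipeline consumes simulated parameter tables directly.

**Seeding.** One `SeedSequence` per subject, split into independent
substreams per scheme; forests spawn one substream per tree from the
master seed, so results are independent of construction order.

## Pupil morphometry

Segmentation thresholds the frame (Otsu by default; pixels at or below
the Otsu value, which skimage reports as the upper edge of the dark
class), labels 8-connected components and keeps the largest dark blob.
Nine parameters are measured: centroid (row/col, origin top-left,
0-based), pixel-count area, minimum-area rotated bounding rectangle
(area, azimuth, aspect ratio), outer contour length (weighted boundary
perimeter), and left/right and top/bottom pixel-count symmetry ratios
about the centroid (pixels exactly on the centroid line excluded from
both halves). Frames with no detectable pupil inherit the previous
frame's parameters; a pupil-less prefix is back-filled from the first
detection, keeping the trace at full length as the normalization
requires.

Two numerical choices deserve note. The bounding rectangle is computed
from pixel centers (shapely's rotating-calipers minimum rotated
rectangle) and its area floored at the pixel count, since a covering
rectangle cannot be smaller than the region it covers; expanding pixels
to unit squares instead would bias the area high by a half-pixel border
(≈5% for a 30×15 ellipse). The azimuth is *not* taken from the raw
rectangle edge: the minimum-area rectangle of a pixelated region pivots
on hull corner cuts, making its angle ill-conditioned (errors of 5–15°
at realistic pupil sizes). Instead the orientation comes from the
second-order central moments — the principal axis, which coincides with
the rectangle's long axis for any elongated convex region and is stable
to well under 1° on rendered ellipses. On 50 random rendered poses the
measured errors are ≤0.1 px (centroid), ≤1.1% (area) and ≤0.4°
(azimuth at aspect ≥ 1.5).

## Defaults and tie-breaks

| parameter | default | note |
|---|---|---|
| frames per trace | 250 | 30 fps, ~8.3 s per scheme |
| slices × slice length | 10 × 25 | must tile the trace exactly |
| LSTM hidden units | 64 | single layer |
| optimizer | Adam, lr 1e-3, full batch | 32 samples make full batch natural |
| stopping | train acc 1.0 or 200 epochs | typically converges in 30–170 epochs |
| trees | 20 | forest size |
| per-node draw | floor(log2(M(N−1))) = 8 | without replacement from unused pool |
| leaf/vote ties | lowest class index | deterministic |
| split ties | lowest (feature, threshold) | deterministic |

Degenerate candidates (tied values, or an empty side at a node) are
skipped without redraw, so a node may see fewer than 8 usable points;
the nominal 372-point pool is preserved for bookkeeping. The per-tree
(not forest-wide) marking scope and the midpoint threshold placement are
deliberate design choices where the procedure admits readings; both are
recorded here as the package's interpretation.

## Known limitations

- The synthetic class models are illustrative; absolute accuracies on
  this cohort do not transfer to clinical recordings.
- No pruning, missing-value handling or categorical splits in the trees;
  the method uses none.
- The LSTM stage has no regularization or early stopping on held-out
  data — by design it memorizes group 1 (training to purity), and the
  stacking plus forest stages are what provide generalization.
- OOB accuracy is computed on group 2 (the forest's own training group),
  while the reported test accuracy uses group 3.
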
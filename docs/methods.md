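# Methods

## Descriptors

**Classic LBP.** The code of a pixel thresholds *p* samples on the circle
of radius *R* against the centre intensity and accumulates Σ S(x<sub>R,n</sub> −
x<sub>0,0</sub>)·2ⁿ. Samples start at angle 0° on the +x axis and proceed
counter-clockwise; non-integer positions are bilinearly interpolated
(on-lattice positions are snapped to exact pixel reads so integer images
produce exact differences). The step function is S(x) = 1 iff x ≥ 1 — a
strict inequality on integer images; the conventional x ≥ 0 form is
available through `threshold=0`, and with it the whole-image code map is
bit-identical to `skimage.feature.local_binary_pattern(method="default")`,
which the test suite uses as an independent reference.

**AvN-LBP.** The (2R+1)×(2R+1) square ring of offsets around the pixel is
partitioned into *p* half-open angular sectors [n·θ, (n+1)·θ), θ = 360°/p,
with the angle of offset (di, dj) taken as atan2(−di, dj) (rows point down
the image, so this is counter-clockwise from +x). Membership over the full
square ring — not a Euclidean disc — is the unique simple rule that gives
exactly 6 offsets per sector at the default R = 3, p = 8, matching the
divide-by-6 sector averages of the worked example. Each sector's mean
x′<sub>R,n</sub> is thresholded against μ<sub>R</sub>, the mean of the p means, with S(x) = 1
iff x ≥ 0; bit *n* carries weight 2ⁿ with n = 0 at the 0° sector.

Two consequences are worth stating. A perfectly flat neighbourhood gives
all differences exactly 0, hence code 2ᵖ−1 — accepted as-is, since it is
deterministic. And because the sector means and μ<sub>R</sub> shift together,
adding a constant to every pixel leaves every code unchanged. To make
that invariance hold *to the bit*, the production code map evaluates the
threshold in integer arithmetic: with integer sector sums S<sub>n</sub>, counts C<sub>n</sub>
and L = lcm(C), bit *n* is set iff p·S<sub>n</sub>·(L/C<sub>n</sub>) ≥ Σ<sub>m</sub> S<sub>m</sub>·(L/C<sub>m</sub>) — exactly
equivalent to the mean comparison but free of float tie ambiguity. The
test oracle re-derives codes independently with rational arithmetic.

Histograms have exactly 2ᵖ bins and count codes only where the full
window fits (no padding — padding would fabricate intensities and distort
histograms), so their mass is (N−2R)(M−2R).

**Worked-example arithmetic.** The reference example of the sector-mean
computation contains small arithmetic slips (its six printed pixels
average to 160.0, not the printed 160.33; its eight printed means average
to 166.6, not 166.26). The final code, 100, is invariant to either
reading, and only the code is used as an exact fixture.

**Noise model.** `add_gaussian_noise` adds zero-mean Gaussian noise with
variance var(I)/10^(SNR/10), then rounds and clips to [0, 255];
SNR_dB = 10·log₁₀(signal variance / noise variance). `snr_db=inf` is the
no-noise sentinel; a zero-variance image takes its signal variance from a
configurable floor (default 1.0). Empirical SNR on 64×64 images is within
0.3 dB of the request.

## Fuzzy ARTMAP

Features are scaled to [0,1] (histograms by their maximum count) and
complement-coded, AI = (a, 1−a), so |AI|₁ = d and the vigilance
denominator is constant. Training presents patterns in order (optionally
shuffled per epoch from a seed): the first pattern of each class founds a
category W = AI; otherwise categories are ranked by the choice function
T<sub>j</sub> = |AI∧W<sub>j</sub>|/(α+|W<sub>j</sub>|) (ties to the lowest index) and scanned in order.
A category resonates if |AI∧W<sub>j</sub>|/|AI| ≥ ρ; on a label match it learns by
the convex fast-learning update W ← β(AI∧W) + (1−β)W, on a mismatch
vigilance is raised to the winner's match ratio + ε for the remainder of
that pattern (match tracking), and an exhausted search commits a new
category W = AI. Prediction takes the label of the argmax-T category, no
vigilance. Under the convex update weights are componentwise
non-increasing, so categories only ever grow (as hyperboxes).

Defaults: ρ = 1.0 (capped internally at 1−10⁻⁹, since exact-containment
vigilance is float-fragile; the operating point is "ρ ≅ 1"), α = 0.001,
β = 0.8, ε = 0.001 (no canonical value exists; any small positive
increment only needs to push past the failed winner), 5 epochs (the
fast-learning network's resubstitution predictions are stable after a few
passes; the suite checks stability under one further epoch). A config key
δ = 0.2 is carried for completeness but deliberately bound to nothing: it
has no defined role in the training dynamics. The additive update
W + β(AI∧W) — which lets weights leave [0,1] — is kept behind
`additive_update=True` for auditability; it is not the default because it
destroys the containment semantics the vigilance test relies on.

## Differential evolution of FAM populations

**Encoding.** DE needs a fixed vector dimension, so a network is encoded
into `catmax` slots of 2d+2 reals: the weight vector, a label gene and a
validity gene. A slot is active iff validity ≥ 0.5; decode clips weights
to [0,1] and rounds label genes to the nearest valid class index.
Encode∘decode preserves predictions exactly.

**Initial population.** Diversity is seeded the way category proliferation
arises in practice: each of N networks trains on a different shuffled
presentation order with vigilance jittered down by U(0, 0.15) from the
baseline.

**Operators.** The working mutation is neighbourhood-to-best:
V = x<sub>r3</sub> + F1(x<sub>best</sub> − x<sub>r3</sub>) + F2(x<sub>r1</sub> − x<sub>r2</sub>), with r1, r2, r3 distinct
members of the top-ranked `neigh_frac` ∈ [0.3, 0.6] of the population and
x<sub>best</sub> the global best (it is listed separately from the pool, so it is
not restricted to it). The four textbook strategies (rand/1, best/1,
rand-to-best/1, rand/2) are provided for comparison. Crossover is
canonical binomial: trial gene = mutant gene iff rand ≤ CR or at the
forced jrand position. (The source formulation prints the inequality the
other way; since CR = 0.7 is quoted as a conventional crossover *rate*,
the canonical direction is the default and the printed dialect is kept
behind a flag.) Selection keeps the member with the smaller fitness; ties
keep the target, making the per-member update elitist and the
best-fitness trace non-increasing.

**Fitness.** The objective couples accuracy pcc ∈ [0,100] and active
category count Na:

    F = |100·catmin − pcc·Na| / ((catmax − Na)·pcc²),

minimized subject to catmin ≤ Na < catmax, with catmin best set to the
number of classes. As literally written (without the absolute value) the
numerator changes sign and the objective diverges to −∞ as Na → catmax at
high accuracy — the opposite of the stated goal of small accurate
networks — so the absolute form is used; the unguarded formula is exposed
as `fitness_raw` for inspection. Na = catmin is allowed (it is the
optimum); the selection direction is minimization throughout.

The absolute numerator still vanishes on the whole curve
pcc·Na = 100·catmin, and the pcc² denominator is too weak to keep the
search off its low-accuracy end: empirically, mutated networks with
scrambled labels (pcc ≈ 10, Na ≈ 100·catmin/pcc) can out-score accurate
ones and win roughly one run in five. The objective is therefore
completed with an accuracy floor as a third feasibility constraint:
a member is infeasible if its pcc falls more than `pcc_tolerance`
(default 2 points) below the best initial member's (or below an explicit
`min_pcc`). This is not an extra heuristic so much as the statement of
the task — shrink the network *without compromising accuracy* — made
executable; with it, the evolved network's accuracy is structurally
within tolerance of the best initial network. Infeasible members of any
kind receive a large finite penalty graded by the violation, keeping a
pull back towards the feasible region.

**Defaults.** F1 = F2 = 1.0, CR = 0.7, neigh_frac = 0.5, N = 10 networks,
30 generations — the smallest population/budget at which the category
compression is reliably visible on the synthetic sets used here.

## Retrieval

Databases index one 2ᵖ-bin histogram per image. Distance is L1 between
max-normalized histograms (the standard choice in LBP retrieval; χ² is a
config option). Without a classifier the whole database is ranked; with
one, the query's class is predicted first and same-class entries are
ranked ahead of the rest (or the answer restricted to the class), which is
the classify-then-search architecture — both modes are exposed because
either is defensible for deployment. Precision@k and recall@k are
aggregated as ARP (mean precision at depth 10) and ARR (mean recall at
depth max(n_relevant, 10)); both depths are config keys (e.g. 25 for
top-25 accuracy).

## Synthetic data

The generator emulates what the pipeline actually consumes: classes with
distinct second-order spatial statistics. Gratings take per-class
orientation (evenly spaced over 180°) and frequency (~0.15 cycles/px,
where LBP-type codes separate orientations cleanly), a random phase per
image and a smooth luminance field (σ = 8 px, sd 10 grey levels) for
within-class variability; random fields take per-class autocorrelation
length (1, 2, 4 px). Intensities are centred at 128 with amplitude 55
(gratings) or sd 40 (fields). Per-image random streams derive from
(seed, class, index), so datasets are reproducible element-wise. Splits
are stratified 40/30/30 per class with largest-remainder rounding, train
taking remainders first, so 10 images split 4/3/3.

What the generator does **not** emulate: anatomical content, intensity
calibration of real scanners, within-class correlation between images, or
class-imbalanced archives. Passing tests therefore demonstrate the
mechanics and the relative behaviour of the descriptors and classifiers,
not clinical-grade retrieval accuracy.

Measured on these conditions (the suite recomputes all of this): AvN-LBP
1-NN accuracy is ≥ classic LBP at 30/20/10 dB (both are at ceiling on
clean gratings), and the margin opens at severe noise — at 0 dB on the
random-field family sector averaging keeps a clear accuracy lead while
classic LBP degrades. Evolution on overlapping Gaussian classes roughly
halves the largest initial category count while holding evaluation-set
accuracy within 2 points of the best initial member.

## Problem sizes and numerical choices

The test suite and acceptance script run on deliberately small instances:
48×48 images, ≤ 12 images per class, 3 classes, DE populations of 6–8 and
10–30 generations, feature sets of 90 points in [0,1]⁴ — sizes at which
every property of interest is already expressed and a full run takes
seconds. Tolerances: exact integer comparisons for codes and histograms;
float comparisons at pytest.approx defaults; the SNR calibration contract
is ±1 dB. Ties are fixed everywhere (lowest category index in FAM,
database order in retrieval, target survives in DE selection) so all runs
are bit-reproducible from their seeds.

## Known limitations

- FAM is order-sensitive by design; only the DEFAM stage mitigates it.
- The slot encoding caps category count at `catmax`; initial networks
  exceeding it are a hard error (raise `catmax` or lower ρ).
- The quotient objective has a pcc·Na = 100·catmin degeneracy (see
  above); the accuracy floor removes it from the feasible region, but a
  user supplying `min_pcc=0` explicitly reintroduces it.
- Retrieval ranks by exhaustive distance computation — appropriate for
  the database sizes here, no approximate indexing is attempted.
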
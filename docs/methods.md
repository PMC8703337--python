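# Methods

## Hypercube conventions

A hypercube is held in memory as a 3-D array in `(line y, sample x, band)`
order with a strictly increasing wavelength vector; all modules rely on
that convention, and the ENVI reader reorders whatever interleave is on
disk (BSQ/BIL/BIP) into it. Band indices shown to users are 1-based (the
convention of instrument software, "band 20"); conversion to 0-based
indexing is confined to the CLI layer. Data type and byte order are always
read from the header, never assumed. When a header lacks a wavelength
list, a synthetic `1..L` index is substituted and flagged on the cube, so
downstream wavelength-window operations fail loudly rather than silently
misinterpreting band numbers as nanometres.

## Reflectance calibration

Raw intensity is converted to reflectance per pixel and band as
`Ic = (Io − Id) / (Iw − Id)`. References may be full cubes or per-band
profiles; full cubes are averaged over the scan axis (y), giving one
response profile per sensor column and band — the natural reduction for a
push-broom instrument, whose fixed-pattern variation lives in the
(column, band) plane. Design points:

- **Degenerate reference pixels** (`|Iw − Id|` below `eps` times the
  dynamic range, default `eps = 1e-6`) produce 0 reflectance and are
  counted in the log rather than propagating infinities into seed means.
- **No clipping**: reflectance above 1 is preserved; specular pixels can
  legitimately exceed the white tile.
- **Order of operations**: calibration happens before band trimming. The
  two commute for the retained bands, but calibrating first keeps the
  reference bookkeeping on the full sensor grid.

Band trimming is wavelength-window based by default (655–1642 nm kept,
both ends inclusive), which on a 268-band 600–1700 nm grid retains
exactly 239 bands. A fraction-based mode (drop `ceil(f·L)` per end,
default f = 0.05) exists but is off by default: the two rules disagree by
one band on that grid (268 − 2·14 = 240), and the wavelength window is
treated as normative.

## Segmentation

The band slice chosen for segmentation (default band 20) is thresholded
with strict inequalities `Imin < I < Imax` (defaults 400/2000 counts),
labelled with 8-connected components, filtered by a strict minimum pixel
count (default 500 at full sensor scale; 50 in the desk-scale
experiments, matching seed areas of roughly 120–400 px there), and
hole-filled per component.

**Overlapping-seed decomposition.** Seeds are convex and close to
elliptical, so a component holding several touching seeds is decomposed
by model selection over ellipse mixtures: for k = 1..max_k (default 6), a
k-component Gaussian mixture is fitted by EM to the component's pixel
coordinates (k-means++ initialisation, 8 restarts, tolerance 1e-4, all
seeded), each component is converted to an ellipse via its covariance
contour — semi-axes equal twice the covariance eigenvalue roots, exact
for a uniformly filled ellipse — and k is chosen to minimise

    score(k) = |component Δ union(ellipses_k)|  +  0.5 · k · sqrt(area)

i.e. coverage error plus a per-ellipse complexity penalty. The penalty
coefficient was calibrated on a 30-scene planted corpus (240 single
seeds, 60 merged pairs): splitting a true single ellipse always worsens
coverage by at least 0.68·sqrt(area), separating a genuinely merged pair
improves it by at least 0.75·sqrt(area), and a spurious third ellipse
gains at most 0.22·sqrt(area), so 0.5 sits centrally between the decision
boundaries. A plain Gaussian AIC is unsuitable here because uniformly
filled ellipses are not Gaussian samples and it systematically
over-splits. Pixels in overlap zones are assigned to the
smallest-Mahalanobis-distance ellipse (ties to the lower index), so the
sub-masks always partition the component; candidate orders that would
create a sub-mask below the minimum pixel count are rejected. Components
under 25 px are returned unchanged. Final seeds are renumbered by the
(top-most, left-most) corner of their bounding boxes.

## Extraction

Each seed yields a bounding-box-cropped hypercube with non-seed pixels
zeroed (padding value 0; no mask band is embedded, keeping the ENVI
output standard) and an arithmetic-mean spectrum over its pixel set. Mean
spectra commute with band trimming. CSV output uses 8 significant digits,
which round-trips to 1e-6 relative tolerance; existing outputs are
skipped unless overwriting is enabled.

## Synthetic scenes

The generator emulates a push-broom acquisition of seeds on a
black-painted platform: background at 0.02 reflectance, ellipse seeds
(semi-axes 8–14 × 5–9 px at the 200×200 desk scale), a halogen-like lamp
spectrum peaking mid-range, white level 3000 counts over dark level 100,
additive i.i.d. Gaussian pixel-band noise (default sd 0.01 in reflectance
units), quantisation to uint16 counts, and 200-line reference cubes with
5× lower noise (references are always averaged in practice). Default
grid: 60 bands over 600–1700 nm; a 640×1200×268 full-sensor preset
exists. Forced overlapping pairs are placed by bisecting the
centre-to-centre distance until the pixel overlap reaches the target
fraction of the smaller seed; all other seeds keep a 2 px separation so
they stay 8-disconnected. Contested pixels belong to the seed whose
normalised ellipse radius is smallest.

Two planted curve families:

- `default_group_curves` mirrors the empirical control/heat-stress
  contrast: a typical seed spectrum (red-edge rise, 1450 nm water dip)
  plus a smooth non-negative offset for the stressed group that stays
  below 0.01 inside 671–771 nm and opens to ≥ 0.03 above 1000 nm.
- `planted_signal_curves` confines the group gap to a chosen interval
  (Gaussian bump, tails < 1e-3 of amplitude at the edges) for
  band-importance recovery studies.

Not emulated: specularity, shadows, point-spread, husk texture,
radiometric drift. Tests passing on these scenes demonstrate algorithmic
correctness and parameter recovery, not robustness to real-instrument
artefacts.

## Dataset splits and classifiers

Seeds are split 80/20 stratified by group. The pixel-level test set is
exactly the pixels of test seeds; remaining pixels split per group into
training (`floor(0.95·n)`) and validation. At the published scale (100 +
100 seeds, 274,641 pixels with 54,392 in test seeds) this bookkeeping
yields 160 training seeds and 104,517 + 104,719 = 209,236 training
pixels.

- **Seed SVM**: PCA (fit on training spectra only, centred on the
  training mean, no scaling — reflectance shares a scale) to 50
  components by default, then an RBF SVM (C = 1, gamma = `scale`). One
  sample per seed, so test accuracy equals seed-group prediction
  accuracy.
- **Pixel SVM**: the same RBF SVM on raw centre-pixel spectra; per-seed
  labels by majority vote — a seed is control iff strictly more than half
  its predicted pixels are control, so an exact tie goes to the stressed
  class (the voting rule is stated for control; the complement, ties
  included, is the stressed side).
- **3D CNN**: one S×S×L patch per seed pixel (S = 5, edge-reflection
  padding at borders keeps one sample per pixel exact), labelled by the
  centre pixel's seed. Architecture: conv3d with 2 kernels → ReLU →
  conv3d with 4 kernels → ReLU → flatten → fully connected (128) → ReLU →
  linear → softmax over 2 classes. Kernels are 3×3×7
  (spatial×spatial×spectral) with stride 1 and no pooling — the smallest
  standard receptive field that two stacked valid convolutions fit into a
  5×5 patch. Biases initialise to zero and weights He-normal (seeded), so
  an untrained network on a zero patch outputs (0.5, 0.5). Training is
  plain minibatch SGD (lr 0.01, momentum 0.9, batch 128, ≤ 30 epochs)
  with validation-accuracy early stopping (patience 5) keeping the best
  weights; everything is derived from one seed and two runs on identical
  inputs are bit-identical. The network is implemented directly in NumPy
  (im2col convolutions, explicit backward pass): at these patch sizes it
  trains in seconds and keeps the dependency surface minimal.

Metrics use the stressed group as positive class: accuracy
(TP+TN)/total, precision TP/(TP+FP), recall TP/(TP+FN), F-score
2TP/(2TP+FP+FN); ratios with zero denominators report 0. The worked
confusion example (TP=15, TN=17, FP=5, FN=3) gives accuracy 80.00%,
precision 75.00%, recall 83.33%, F-score 78.947…% (78.94% when truncated
to two decimals).

## Wavelength importance

A LightGBM classifier (leaf-wise growth with depth constraint: 200 trees,
31 leaves, max depth 8, learning rate 0.1) is trained on pixel spectra;
a band's importance is its split count over all trees divided by the
total split count, ranked descending with wavelength-ascending
tie-breaks. Two stabilisers are set beyond the tree-shape parameters:
`feature_fraction = 0.7`, because neighbouring bands are strongly
correlated and without per-tree feature subsampling a single best band
absorbs every split; and `min_split_gain = 1e-3`, because once boosting
has exhausted the class signal, zero-gain splits are tie-broken by column
order and pile up on whichever band happens to come first — inflating an
arbitrary wavelength's count by hundreds of bookkeeping splits. Gain
importance is available as an option.

## Experiment problem sizes and statistical checks

The recovery experiments run at desk scale: 200×200 scenes, 60 bands, 12
seeds each; the classifier comparison pools 4 scenes (≈ 48 seeds, ≈ 11k
pixel samples) per replicate and 10 replicates; segmentation recovery
uses 20 scenes with two ~20%-overlap pairs each; importance recovery uses
10 single-scene replicates. All seeds are explicit.

Spectral conservation compares recovered per-group mean reflectance to
the planted curves band by band, in units of the standard error of the
group mean. That SE combines the pixel-scatter term with the
calibration-reference uncertainty propagated by the delta method
(reference-profile errors are shared by every pixel in a sensor column,
so they are invisible to pixel scatter; their variance is estimated from
the reference cubes' own line-to-line spread). A 3-SE band is a 3-sigma
test applied at ~106 band×group comparisons, so even perfect recovery
exceeds it somewhere about a quarter of the time; the check therefore
bounds the number of 3-SE exceedances by the noise-only binomial 99.9%
envelope (≤ 3) and additionally caps the worst band at 5 SE and 2×10⁻³
absolute reflectance — any systematic calibration bias violates all
three long before it matters scientifically.

## Known limitations

- The ellipse decomposition assumes convex, roughly elliptical seeds;
  strongly non-elliptical shapes (some maize kernels) may over-split.
- The scene generator's noise is i.i.d.; real sensors show spectrally
  correlated noise and striping, which would widen the conservation
  envelopes.
- The 3D CNN is sized for 5×5 patches; larger patches work but the NumPy
  implementation is not optimised for them.
- Batch glob resolution implements filename globs (`*.hdr`), not full
  regular expressions.
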
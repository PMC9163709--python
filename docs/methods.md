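# Methods

## Record model

An iEEG record is one stored event from an implanted responsive
neurostimulator: up to 4 channels of samples at 250 Hz (Nyquist 125 Hz),
duration 30–240 s (typically 90 s), a storage trigger time and a trigger
class (long episode, scheduled, magnet, saturation). Channels a device
did not record are represented as absent, not zero-filled; zero
substitution happens only where channel features are combined into a
record-level vector, so "no signal" and "flat signal" stay
distinguishable upstream.

## Synthetic patients

The simulator (`synthio`) generates patients whose records have the two
statistical properties the pipeline assumes: a small set of stereotyped
morphologies per patient, and distinct morphologies across patients.
Each patient owns a list of morphology templates; each template emits
`records_per_template` records, every record labelled with its template.

Event classes and their default parameters:

| class | content | key defaults |
|---|---|---|
| `baseline` | pink (1/f) + 20% white noise | 40 µV RMS |
| `interictal_spike` | noise + sparse biphasic transients (Gaussian-derivative, width 60 ms) | 20 events/min, 300 µV |
| `seizure_hf_band` | noise + Tukey-windowed chirp sweeping a high-frequency band | band 50–75 Hz, 35 s ictal, 150 µV |
| `seizure_harmonics` | noise + harmonic stack (fundamental + overtones, 1/k amplitudes) | f0 10 Hz, 3 harmonics, 30 s ictal |
| `stim_artifact` | periodic biphasic square pulses (instantaneous slew) | every 5 s, 100 ms, 1000 µV |
| `saturation` | large 2 Hz drive clipped at symmetric rails | ±400 µV rails |

Each template carries a length-4 involvement mask (uninvolved channels
get background only) and an amplitude scale. Long-episode records trigger
30 s into the record so the crop rule is exercised; scheduled records
trigger at the start. Determinism: every record/channel draws from a
`SeedSequence` spawned from (patient seed, template index, record index,
channel index), so identical specs reproduce bit-identical samples.

What the simulator does **not** emulate: biophysically realistic seizure
dynamics (onset propagation, evolving rhythms), amplifier
characteristics, electrode drift, circadian structure, or the long-tailed
morphology diversity of real patients. Tests passing on this data show
the pipeline's mechanics are correct and that it recovers planted
structure under the stereotypy assumption; they are not evidence about
retrieval quality on clinical recordings.

## Preprocessing

Records in the 80–100 s range pass through unchanged. Shorter records are
padded to 90 s by duplicating the first `90 − L` seconds of the record
onto the beginning (tiling from the start when the record is shorter than
the deficit). Longer records are cropped to `[trigger − 30 s,
trigger + 60 s)`; when that window overruns a record boundary it slides
so the output is always exactly 90 s. A strict mode (`crop_above_target`)
crops anything above 90 s instead. Records lacking trigger metadata (NaN
offset, e.g. bare EDF imports) crop around the midpoint with a warning.

Stimulation-artifact rejection is a per-channel slew-rate detector:
samples where the absolute first difference exceeds 8 × the scaled median
absolute deviation of the differenced signal are blanked with a ±20 ms
guard and bridged by linear interpolation. This simple robust-threshold
detector targets device pulses, which are orders of magnitude steeper
than physiological activity; it makes no attempt at template subtraction
or detection of low-slew artifacts.

## Spectrograms

Power spectrograms use a Hann window of 256 samples, hop 128 (50%
overlap), giving `⌊(N − 256)/128⌋ + 1` frames × 129 frequency rows over
0–125 Hz (174 × 129 for a 90-s record). Power is mapped to dB, clipped to
the per-image [1, 99] percentile range, normalized to [0, 1], passed
through a fixed 256-entry jet lookup table computed in-package from the
classic piecewise-linear segment definition, and bilinearly resized to
224 × 224. Low frequencies sit at the bottom row. Per-image percentile
normalization makes the image invariant to uniform amplitude scaling (to
within one LUT step); the choice trades absolute amplitude information
for robustness across devices and gains.
A constant signal renders as the colormap's low endpoint everywhere.
Tiled record images place channels 1–4 row-major at 112 px; absent
channels are black tiles.

## Feature extraction

Convolutional backends share one contract: a 224 × 224 × 3 image in, a
C × H × W feature map from the final retained convolution out. The trunk
is a compact numpy CNN — 4× average-pool downsample, then three 3 × 3
stride-2 convolution + ReLU blocks (16, 32, 64 channels) — mapping to a
64 × 7 × 7 map; `truncate_layers` removes blocks from the end, exposing a
spatially larger, shallower map. Three backend kinds: `random_init`
(seeded He-initialized weights, untrained), `classifier_surrogate`
(trained in-package on labelled synthetic spectrograms to separate
seizure from non-seizure images, then frozen), and `generic_pretrained`
(fixed weights loaded from an `.npz`). Record-level features concatenate
the four flattened channel maps in channel order, zero-filling missing
channels (total length 4 × C × H × W).

The hand-engineered baseline is 28 spectral-power features: the plain
rectangular-window periodogram summed over the half-open bands 0–4, 4–8,
8–12, 12–25, 25–50, 50–125 and 0–125 Hz, per channel. Because the six
sub-bands partition [0, 125), their sum equals the total band exactly up
to floating-point error.

## Within-patient clustering

Per patient: PCA to `min(50, n − 1, dim)` components (no whitening),
t-SNE to 2D (perplexity `min(30, (n − 1)/3)`, PCA initialization, exact
method below 1000 records, fixed seed), then a Bayesian Gaussian mixture
with full covariances, a Dirichlet-process weight prior with
concentration `1/n_components`, up to 500 iterations and 5 seeded
restarts keeping the best variational lower bound. The restarts matter:
a single variational fit can settle on a local optimum that describes one
Gaussian blob with two components; with restarts a single planted blob
yields one effective cluster and well-separated blobs are recovered
exactly. The component budget is `max(⌊n/500⌋, 15)` (floor division;
the heuristic's worked examples are exact multiples so rounding is
unobservable there, and floor is the conservative reading). Assignments
are maximum posterior responsibility; the effective cluster count is the
number of distinct assigned components. Each non-empty cluster's
representative is the member record with minimal Euclidean distance to
the cluster's mean 2D coordinate, ties broken to the lowest record id.

PCA is fitted per patient on that patient's records only; the
cross-patient index fits its own PCA on search centroids.

## Triplet mining and contrastive training

Anchors are cluster centroids. Same-cluster triplets: positives are the
anchor's 3 nearest same-cluster records in the 2D mining space; for each
(anchor, positive), negatives are the next 5 same-cluster records in
distance rank beyond that positive — the nearest-beyond-p reading keeps
these semi-hard rather than maximally easy. Different-cluster triplets:
the 5 nearest same-cluster records as positives, 10 negatives sampled
seeded and without replacement from the patient's other clusters. Counts
truncate in small clusters; single-cluster patients yield no
different-cluster triplets. Mining distances are Euclidean in the
within-patient t-SNE plane.

The taxonomy on distances `d_ap`, `d_an` with margin `m`: easy iff
`d_ap + m < d_an`, hard iff `d_an < d_ap`, else semi-hard. The hinge loss
is `max(0, m + d_ap − d_an)`; default margin 1.0 (configurable — no
reference value exists).

The embedding model maps a tiled record image to an m-vector (default
m = 256) through the same trunk plus global average pooling and a linear
head. Training minimizes mean hinge loss over seeded shuffled batches of
16 triplets (48 images) with Adam; the reference learning rate default is
10⁻⁵. Early stopping monitors validation loss on triplets from held-out
patients with patience 5 and always restores the best-validation-epoch
weights. No output normalization is applied by default (flag available);
gradients are taken on the raw embedding. The desk-scale test problem
(two training patients, one held-out, ~260 triplets, ≤5 epochs) uses a
10⁻³ step so descent is visible within its budget; at 10⁻⁵ the same
problem moves too little in five epochs to assert anything.

## Cross-patient retrieval

Query augmentation uses the dihedral orbit of the channel ordering
(1, 2, 3, 4): 4 cyclic rotations plus their reversals — exactly 8
orderings including the identity, preserving channel adjacency in the
stacked/tiled image. The orbit is closed under composition, so querying
with an already-permuted record pools over the same variant set and
returns the same result.

Feature method: per-channel maps of the search centroids are combined and
reduced by a PCA (≤50 components) fitted once on the centroids and saved
in the index. At query time each variant's combined features pass through
the saved PCA (variants permute per-channel feature blocks, which is
identical to re-rendering the permuted record); search points and the 8
variant points are jointly embedded to 2D by seeded t-SNE and each
variant's k nearest search neighbours are collected. A `pca_50d` mode
runs kNN directly in the PCA space, trading fidelity to the depicted
2D flow for speed and embedding stability. Contrastive method: each
variant's tiled image is embedded and all centroids are ranked by
Euclidean distance.

Pooled (variant, neighbour, distance) tuples are sorted ascending by
(distance, patient id, record id), deduplicated keeping each record's
best distance, and truncated to the top k = 5 unique records.

## Numerical and design notes

- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; fixed seeds give byte-identical fixtures,
  cluster assignments, mined triplets and loss histories.
- t-SNE joint embedding is recomputed per query (the 2D plane has no
  out-of-sample transform); this is O((n_search + 8)²) per query and is
  the main retrieval cost at scale — the `pca_50d` mode avoids it.
- The EDF exporter writes plain 16-bit EDF (1-s data records,
  integer-second durations); values round-trip to within the 16-bit
  quantization step. Annotations and EDF+ are out of scope.
- Degenerate inputs: all-identical feature vectors embed to coincident
  points with a warning; records with no trigger metadata crop around
  the midpoint with a warning; artifact rejection that would blank nearly
  everything leaves the channel unchanged with a warning.
- Test problem sizes (30-s records, 8–20 records per template, 64 × 7 × 7
  feature contract, m ≤ 32 embeddings, ≤6 training epochs) are chosen so
  the whole suite trains every network from scratch in about a minute on
  one CPU while still exercising every contract at full 224-px image
  size.

## Known limitations

- No deep-learning framework is used; the in-package numpy CNN is small
  by design. The reference-scale architecture (2048 × 7 × 7 maps) is
  supported by the feature contract but no pretrained weights ship with
  the package, so `generic_pretrained` requires user-supplied weights.
- Retrieval quality claims are limited to planted-structure recovery on
  synthetic data (see `tests/test_acceptance.py`); clinical performance
  is untested here and the original study's qualitative comparisons on
  real patient queries are out of scope.
- The artifact detector is a stand-in for device-specific rejection; it
  will miss low-slew artifacts and may clip genuinely steep epileptiform
  transients at extreme amplitudes.
- Cross-patient triplets and online (in-training) mining are not
  implemented.
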
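# Methods

## Model

MSSC treats complexity as self-dissimilarity across spatial scales. The
image is decomposed by the 2-D discrete Fourier transform (unnormalised
forward, `1/N²` on the inverse) and coarse-grained by *ideal* low-pass
filtering: every coefficient at centred frequency distance `≥ r` is zeroed
and the image reconstructed from the remainder. Ideal filters are orthogonal
projections, which gives the implementation three exact identities used as
self-checks throughout the test suite:

- **Projection nesting** — filtering at `r2` then `r1 ≤ r2` equals filtering
  once at `r1`; the whole stack is therefore cut from the original image's
  spectrum rather than re-transformed iteratively (mathematically identical,
  numerically cleaner).
- **Parseval consistency** — each partial complexity equals half the mean
  spectral energy of the ring removed at that step.
- **Telescoping** — the full-window sum equals
  `½·(O(P_0,P_0) − O(P_S,P_S))`.

The partial-complexity form `C_k = |O_{k,k+1} − ½(O_{k,k} + O_{k+1,k+1})|`
with `O` the pixel-count-normalised inner product is the overlap-based
definition from the measure's statistical-physics lineage; for low-pass
stacks it reduces to "energy lost at the step", which is the reading used
in all closed-form tests (a pure cosine of amplitude `A` contributes exactly
`A²/4` to the step whose ring holds its frequency). The overlap functional
is a module-level function, deliberately easy to swap, and the coarse-grain
module keeps filtering behind a narrow interface so alternative
coarse-graining back-ends (block averaging, wavelets) can be added without
touching the complexity code.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| canonical side `N` | 512 | px | square working size; images are resized anisotropically (no crop/pad) |
| steps `S` | 10 | — | enough rings to resolve scale structure without empty rings at `N = 512` |
| radius schedule | `N^(1−k/(S−1))`, k = 0…S−1 | px (frequency-index distance) | "evenly on a log scale" over [1, N]; log-spacing over [0, N] is ill-posed, so the geometric sequence on [1, N] is the closest well-defined reading. `r = N` passes everything (first step is a no-op), `r = 1` keeps only the mean |
| cutoff rule | keep `distance < r` | — | strict inequality fixes tie-breaking for coefficients exactly on the circle |
| scale window | steps 2–7 inclusive | — | drops the two finest and two coarsest of 10 steps, the scales that track artefacts and global layout rather than content; fully configurable, and `window_sweep` searches all contiguous windows empirically |
| channel weights | per-channel mean intensity | — | "intensity" is taken as the arithmetic mean of the channel in [0, 1]; weights are not renormalised, so brighter channels contribute more |
| pixel range | [0, 1] on ingest | — | dividing by the bit-depth maximum makes scores comparable across encodings; by the quadratic scaling law a [0, 255] convention would multiply every score by 255² |

Filtered grids may overshoot [0, 1] slightly (Gibbs ringing) and are never
clamped — clamping would break the projection identities. Clipping happens
only in the display-export path.

## Synthetic data

The generator emulates images with *known* spectral content: constants,
uniform white noise, band-limited noise (spectrum zeroed outside a stated
ring, then affinely rescaled into [0, 1] — the rescale touches only DC and a
global gain, so spectral support is preserved and tests compensate via the
quadratic scaling law), checkerboards, single cosines, linear ramps, and
pixel-wise-mean composites. `annulus_noise_mixture` goes further and fixes
the energy of every coarse-graining ring explicitly, so each scale's partial
complexity can be dialled independently across images.

What passing tests show: the transform chain, the spectral identities, the
windowing/aggregation arithmetic, and the statistical behaviour of the
correlation harness are correct. What they do not show: anything about how
the measure tracks *human* ratings of natural images — synthetic fixtures
have none of the semantic, photometric or compositional structure of
photographs or art, and validating against a rated image set requires
external data fed through `mssc compute` / `mssc evaluate`.

## Evaluation harness

Ratings are joined to computed scores on `image_id` within category;
agreement is the Pearson correlation, per category, for the windowed total
and for each step's partial complexity. Zero-variance cells return an
explicit `None` marker rather than NaN so category means stay interpretable.
Published analyses of this kind pick the scale window by inspecting
per-step correlation plots; `window_sweep` formalises that as an exhaustive
search over contiguous windows maximising the cross-category mean `r` under
a single common window — an explicit, reproducible extension of the manual
step, not a claim about any particular study's procedure. Argmax ties break
toward the widest window, then the smallest `lo`, for determinism.

The planted-window benchmark (`mssc.benchmark`) is the end-to-end
statistical check: 2 categories × 100 images of ring-mixture noise with
per-ring gains drawn from U(0.2, 1), ratings defined as the true windowed
total over steps 2–7 plus Gaussian noise at half the signal's standard
deviation. At those settings the expected attenuation is
`√(Var_s/(Var_s+Var_n)) ≈ 0.894`, every candidate window that adds or drops
a step pays a measurable correlation cost, and the sweep recovers (2, 7)
essentially always over 100 replicates. Gains below 0.2 are avoided so no
scale degenerates to near-zero variance, which would make adjacent windows
statistically indistinguishable.

## Numerical choices

- FFT via numpy; forward/inverse conventions match the definition above
  exactly (verified against literal O(N⁴) double sums on 16×16 grids at
  1e−10 relative tolerance).
- The low-pass mask is radially symmetric, so conjugate symmetry of real
  images' spectra is preserved; the inverse transform's imaginary residue is
  checked against `1e−8 ×` the pixel range and then discarded. A violation
  raises rather than silently yielding complex output.
- Resizing uses bilinear interpolation with Gaussian anti-aliasing when
  downscaling (spurious aliasing energy would inflate fine-scale partial
  complexities); resizing to the current size is an exact no-op, making the
  operation idempotent at the target size.
- Constant images score exactly 0.0, not approximately: the FFT of a
  constant has exact zeros off DC in floating point, and the overlap algebra
  then cancels exactly.
- Batch CSV outputs contain no timestamps and are written in sorted image
  order, so re-running a batch is bit-identical; logs (with timestamps) go
  to stderr only.
- Study sizes: identity checks run on a 24-fixture corpus at 64 px; the
  planted-window study uses 64 px images so that 100 replicates × 200 images
  complete in about a minute. All structural identities are
  resolution-independent, and 64 px leaves 8 of 10 rings non-empty.

## Limitations

- 16-bit output is implemented for grayscale PNG only (16-bit RGB PNG is
  not supported by the imaging backend); 16-bit *input* works for grayscale.
- Non-square images are stretched to the square, altering aspect ratio, on
  the reading that a fixed canonical grid matters more than isotropy; crop
  or pad upstream if that is wrong for your data.
- Only sharp-cutoff Fourier coarse graining is implemented; tapered filters
  (Gaussian, Butterworth) would break the projection identities the tests
  rely on and are intentionally out of scope, as are block-averaging and
  topology-based coarse graining.
- Correlations are reported as magnitudes; no significance testing or
  confidence intervals, and no conversion of pairwise comparisons into
  ratings — the harness consumes continuous scores as given.
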
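# Methods

This note documents the model and procedure behind `wormviz`, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic tests do and do not demonstrate about real
recordings.

## Pipeline

The working representation is a `FrameStack`: a `(time, row, col)` float
array with intensities on $[0, 1]$ regardless of the source bit depth
(8-bit values map to $v/255$, 16-bit to $v/65535$). Normalizing once at
load time makes the gain/offset rendering parameters independent of the
camera's bit depth. Color input is reduced to BT.601 luminance
($0.299R + 0.587G + 0.114B$), the de-facto video standard. Timestamps
are synthesized as $t_i = i/\mathrm{fps}$ when the container provides
only a frame rate; a user-supplied fps always beats container metadata,
which is frequently wrong for timelapse material.

Processing order is fixed: brightness normalization → vignetting
correction → average subtraction → rendering. The average used for
subtraction is recomputed on the corrected stack, which keeps the
static-scene → exactly-zero property of the subtraction intact.

### Brightness normalization

Each frame is multiplied by $\bar{m}/m_t$ where $m_t$ is its mean
intensity and $\bar{m}$ the grand mean (or a user target). This removes
global flicker (lamp drift, auto-exposure) before any spatial
correction. An all-black frame cannot be rescaled and is reported as an
error with its index.

### Vignetting correction

The shading estimate is the Gaussian-blurred temporal average frame,
floored at `epsilon` (default $10^{-3}$, guarding division in dark
regions outside the plate) and rescaled to unit spatial mean so the
correction preserves global brightness. The default blur scale,
$\sigma = \min(H, W)/8$, is far above the worm scale: the correction
must only touch low spatial frequencies, otherwise it would erode the
worms themselves.

Boundary handling matters more than it appears. Even (mirror) reflection
flattens the shading gradient at the frame edge, which biases the blur
as far as $\sim 2\sigma$ into the frame — with $\sigma$ at an eighth of
the frame, that is a quarter of the image. We therefore pad with
*antisymmetric* (odd) reflection, which extrapolates the local slope and
is exact for linearly varying shading; the pad width is
$\min(4\sigma, \min(H,W)/2)$, the cap ensuring that an absurdly large
$\sigma$ still converges to a uniform (no-op) field. On a flat scene
degraded by a 40% radial vignette this reduces the spatial coefficient
of variation by a factor of ~60 (an even-reflection blur manages only
~4). The correction is optional: a well-built imaging setup should not
need it.

### Average subtraction

$S_t = |I_t - \bar{I}|$. The temporal mean is computed anchored at the
first frame, $\bar{I} = I_0 + \mathrm{mean}_t(I_t - I_0)$, which is
algebraically identical but makes the mean of a static stack *bit-exact*
— a static scene subtracts to exactly zero, not to $10^{-17}$ residue.
The absolute value gives brightfield/darkfield symmetry: inverting all
intensities leaves $S_t$ unchanged to the last bit of rounding.

### Enhancement, color, fade, projection

Each subtracted frame is enhanced as
$E = \mathrm{clip}(g S - o, 0, 1)$: pixels with $gS \le o$ become
exactly zero, which is what removes low-amplitude sensor noise.
Defaults are $g = 10$, $o = 0.05$. Note the interaction with window
length: a maximum projection accumulates the maximum of the noise over
the window, so full-recording stills of noisy footage want a larger
offset than 20-second windows (the README example uses 0.3 for a
300-frame still at noise $\sigma = 0.01$).

Within a window of $n$ frames, frame $i$ (0 = oldest) gets a fade
weight: with $m = \mathrm{round}(f \cdot n)$ for fade fraction
$f \in [0, 0.5]$, the weight ramps $0 \to 1$ over the oldest $m$ frames
and is 1 elsewhere. Only the old end fades — old track segments vanish
gradually across successive output frames — while the newest frame
always enters at full strength, so the animal itself is never dimmed;
$m$ is capped at $n - 1$ to keep that guarantee even for degenerate
windows.

The projection selects, per pixel, the frame with maximal weighted
enhanced intensity $E_i w_i$, breaking ties toward the **later** frame
(recent behavior wins). The output pixel is that scalar times the
colormap value at the winning frame's normalized time. Selecting one
winning frame and then coloring — rather than taking per-channel maxima
— avoids blending colors from different times into hues that never
occurred. Normalized time $u$ spans the full recording for stills and,
by default, the window for videos (coloring encodes recency); global
time coloring is available via `time_norm="global"`.

Colormaps are piecewise-linear in linear RGB between control points; the
rendered pixel is intensity × color, and linear RGB keeps that product
interpretable. Built-ins: `blue_red` and `cyan_magenta` (sequential),
`blue_white_red` (diverging, for pre/post-intervention recordings),
`green_yellow_red`, and `constant_white` (no temporal encoding). Custom
maps load from plain-text `u r g b` rows.

Video windows are trailing: the output at frame $t$ covers frames
$[t - n + 1, t]$ with $n = \mathrm{round}(\mathrm{window\_s} \cdot
\mathrm{fps})$, truncated (not padded) at the start of the recording to
avoid phantom black history. A window longer than the recording degrades
to a single full-recording frame with a warning.

## I/O

Lossless storage uses multi-page ImageJ-style TIFF (which carries the
frame rate as metadata and round-trips 8-bit pixels exactly) or numbered
PNG sequences; these are the package's native interchange formats and
need no external codec. Containers requiring an ffmpeg backend are read
and written through imageio only when such a backend is present; the
lossless flag refuses lossy codecs with a pointer to the TIFF/PNG path.
All rendered output is quantized to 8 bits.

An advisory acquisition check warns when
`max_speed × median frame interval > worm_length` — a worm moving more
than one body length between frames leaves dotted rather than continuous
trails. One frame per second is a sensible rate for plate-scale assays.

## Synthetic recordings

`SimScene`/`simulate` generate the fixtures for every test. Each worm is
an isotropic Gaussian blob (default $\sigma = 2$ px, peak 0.5) — a
deliberate simplification: trails survive even sub-worm pixel
resolution, so blob-level realism suffices for trail-level tests. Motion
is a two-state Markov chain between *roaming* (default 5 px/s) and
*dwelling* (1 px/s), switching with symmetric probability 0.05 per
second (converted per frame as $1 - (1-p)^{1/\mathrm{fps}}$), the
minimal mechanism producing the roam/dwell contrast seen in real
recordings. Headings diffuse as a wrapped Gaussian walk
($\sigma = 0.3$ rad/frame roaming, 4× that dwelling); positions reflect
at the frame boundary. Rendering adds a radial-quadratic vignette
($1 - s\,(r/r_\mathrm{max})^2$, the first-order lens model), constant
background (0.1 darkfield), and additive Gaussian sensor noise
($\sigma = 0.01$). Defaults — 256 px frames, 1 fps, 300 s, five worms —
describe a desk-scale version of a plate assay at roughly 4 px per worm.
Output is bit-identical under a fixed seed.

What the simulator does **not** emulate: elongated body posture and
self-occlusion, lawn texture and lawn-edge behavior, chemotaxis
gradients, compression artifacts, illumination flicker beyond what
brightness normalization models, and worm–worm collisions. Passing tests
therefore demonstrate the correctness of the *pipeline mathematics*
(subtraction, correction, projection, coloring, determinism) on
worm-like inputs, not segmentation-grade robustness on arbitrary real
footage.

`ideal_trail_mask` (union of disks around ground-truth centroids) is the
oracle for coverage tests: with default gain/offset on noise-free
5-worm recordings, every trailing 20 s and 60 s window lights 100% of
its ground-truth centroid pixels.

## Numerical and degenerate-input choices

- All stages clip to $[0, 1]$; the representation stays closed.
- Argmax ties → later frame, everywhere, so results are deterministic.
- A one-frame window gets $u = 1$ (it is the newest frame).
- Fewer than two frames is an error for any averaging stage.
- `round` is round-half-up for window sizes and fade ramps, avoiding
  the platform dependence of banker's rounding.
- Windows are per-output recomputed; no incremental state, so stride
  and window changes cannot desynchronize.

## Problem sizes

The test suite and the acceptance script run on 16–256 px frames and
40–300 frame recordings — sizes at which every check, including the
brute-force projection oracles and per-window coverage over all 300
windows, completes in well under a minute on one CPU. The pipeline
itself is vectorized per window and handles 1200 px frames; memory for a
full-float stack of $T$ frames at $H \times W$ is $8THW$ bytes, so
hour-long high-resolution recordings are best processed with a stride or
in chunks.
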
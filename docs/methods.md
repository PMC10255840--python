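# Methods

## Scope and model

`fallradar` studies whether the *direction* of a fall — forward,
backward, left, right while walking, or a fall from standstill — can be
recovered from the range–time (RT) and Doppler–time (DT) signatures of
a single-channel FMCW radar, using a two-stage map denoiser (PFE) and a
dual-branch CNN. No public dataset of directed falls with radar
baseband exists, so the package carries its own simulator and the whole
chain is validated on synthetic echoes.

### Radar signal model

The person is a single torso-dominant point scatterer at radial
distance d(t). After dechirping, chirp *m* (slow time t_m) contributes

    z_m(t) = a(d) · exp( j·2π·β·(2d/c)·t + j·4π·f_c·d(t_m)/c )

with amplitude a(d) = 1/d² (free-space two-way spreading; the radar
equation's constants are absorbed into the unit target). The slow-time
phase term is what carries Doppler: its instantaneous frequency is
(2 f_c / c)·(dd/dt), negative while approaching. Limb micro-Doppler,
antenna patterns, multipath and transmitter phase noise are not
modeled; the classifier consumes gross range/Doppler *trends*, which a
point target reproduces. Thermal noise is complex white Gaussian at a
configurable SNR relative to the mean echo sample power; a static
reflector at fixed range (default amplitude 0.02, range 1.2 m) provides
zero-Doppler clutter; sparse speckle outliers (Bernoulli per map cell,
default rate 0.005, +20 dB over the map mean) corrupt the finished maps
to exercise the denoiser.

Radar constants follow a 60 GHz device sweeping B = 3.015 GHz at
β = 50.259 MHz/µs with 256 samples per chirp at 5 MHz, 128-chirp
frames, 100 µs inter-chirp idle (chirp interval 160 µs). Only 51.2 µs
of the 60 µs ramp is sampled, so the DFT range-bin spacing follows the
distance equation d = c·f_b/(2β) with Δf_b = f_s/N: 5.83 cm/bin,
unambiguous range 7.46 m. Frames repeat every 50 ms (a typical
people-monitoring duty cycle; the burst occupies 20.5 ms of it). One RX
channel is synthesized: extra RX channels add nothing to RT/DT maps
formed without angle processing.

### Trajectory templates

All five classes share the same skeleton: a constant-speed walk phase
(default 1 m/s ± 10 % jitter), a fall of duration U[0.6, 1.2] s whose
radial excursion follows a smoothstep ramp, and stillness afterwards.
The class determines the excursion's direction and size:

| class     | range trend at fall (walking toward) | excursion (m, 1.75 m subject) |
|-----------|--------------------------------------|-------------------------------|
| forward   | continues decreasing, steeper        | 0.90 |
| left      | continues decreasing, steeper        | 0.30 |
| backward  | reverses: decreasing → increasing    | 0.70 |
| right     | reverses: decreasing → increasing    | 0.25 |
| standstill| flat, then monotone excursion        | 0.50 |

Walking away mirrors every sign, and the toward/away variants of each
direction are merged into one label. Excursions scale with subject
height as h/1.75 (taller subjects displace further, which is what makes
them easier to classify) with ±10 % jitter. Fall onset is drawn from
U[1.8, 3.0] s inside a 5.0 s observation window — long enough for a
clear walk phase, a complete fall, and a post-fall rest segment, while
keeping one data cube at 12 800 chirps × 256 samples. Start distances
are drawn (and clamped) so the target stays inside (0.2, 7.0) m.

### Map formation

RT: per-chirp 256-point DFT, magnitude squared, power averaged over
each frame's burst (one column per frame), dB with a floor at
max − 60 dB. DT: the complex range profiles inside an activity gate
(bins whose slow-time magnitude variance exceeds the median — this
drops static clutter and empty bins) are summed per chirp; a Hann
window of 32 chirps, hop 32, 64-point FFT gives the spectrogram, in dB
magnitude with the same floor. Doppler bins span ±3.125 kHz
(±7.8 m/s); the 195 Hz resolution is ~0.5 m/s, adequate for gait
(~±400 Hz) and falls (~±1 kHz). Non-overlapping 32-chirp windows align
with the 128-chirp bursts, so no window straddles a frame gap. Both
map axes are stamped with wall-clock chirp times so RT and DT share a
physical time axis.

Per-range mean subtraction is available as optional clutter
suppression but is off by default: subtracting the slow-time mean
redistributes the energy of anything that dwells at one range —
including the person lying still after the fall — into a constant
ghost line across all times, which corrupts ridge trends. The variance
gate in the DT path handles static clutter without this artifact.

### PFE

Thresholding uses P_th = (1−a)·mean + a·(max+min) verbatim, with cells
below P_th set to the map minimum (keeping dB semantics). On dB maps
floored at max−60, a = 0.30 puts P_th roughly 20 dB above the floor:
background noise is flattened, the target ridge survives. `a` is a
per-map-kind constant (the same default for RT and DT); values near 1
can exceed max(P), which is documented behavior of the verbatim
formula. The Hampel filter then runs along each feature bin's time
series with K = 5, n_th = 3, scale 1.4826·MAD, truncated windows at the
boundaries, strict-inequality replacement (so exact-median samples
survive even when the local MAD is zero). Isolated speckle that
survived the threshold is pulled to the local median; smooth ridges
pass unchanged. The ordering (threshold, then Hampel) matters: the
threshold first removes the diffuse noise floor, leaving the Hampel
statistics dominated by structure.

### Classifier

Each branch is Conv(→16,3×3) → MaxPool2 → Conv(→32) → MaxPool2 →
Conv(→64) → MaxPool2 → Conv(→128) with valid (no-padding)
convolutions and ReLU after every convolution; a 54×54×3 input
flattens to exactly 1×1152, and the two branches concatenate to 1×2304
before a fully connected softmax over 5 classes. 54×54 is the unique
common input size consistent with that flatten under valid 3×3
convolutions (128 channels × 3×3). A five-way sigmoid output would
contradict single-label classification, so the head is softmax with
cross-entropy. Maps are min–max normalized (a global dB offset
cancels), bilinearly resampled to 54×54, and replicated to three
channels — grayscale replication avoids smuggling a colormap into the
features.

Training: Adam (β₁ 0.9, β₂ 0.999) at learning rate 5·10⁻⁴, 50 epochs,
step decay ×0.5 every 10 epochs (the accuracy/loss curves flatten
after ~10–20 epochs), batch 32, stratified 80/20 split; the 20 % split
is never touched by updates and doubles as the held-out evaluation
set. The network and its gradients are written directly on numpy:
im2col convolutions as GEMMs in NHWC layout, fold-based (col2im) input
gradients, gradient skipping for each branch's first layer. Backprop
is verified against central differences in float64 (agreement ~1e-9)
and the convolution against `scipy.signal.correlate`. With fixed seeds
the entire run is bit-reproducible on one machine.

## Numerical choices

* Baseband synthesis builds the fast-time phasors by repeated doubling
  (exp recomputed exactly at each doubled phase), accurate to ~1e-5,
  ~5× faster than elementwise `exp` on one core; noise comes from
  PCG64DXSM streams derived per sample from the master seed.
* Max-pool backward splits the gradient evenly across tied maxima (the
  exact subgradient); after ReLU, ties essentially occur only at zeros
  where the upstream ReLU blocks flow anyway.
* A degenerate constant map preprocesses to an all-0.5 image with a
  warning rather than an error.
* Hampel windows are truncated (not padded) at series boundaries.

## What the simulation does and does not show

The synthetic study demonstrates that the pipeline — maps, PFE, CNN —
recovers fall direction when the class-conditional range/Doppler trends
hold, and that PFE cleaning does not hurt (and helps under heavy noise
and speckle). It does **not** demonstrate robustness to limb
micro-Doppler structure, multiple movers, torso orientation effects, or
real clutter environments; the point-scatterer classes are more
separable than real falls, and measured accuracies here (≈99 % at 200
samples/class, 15 dB SNR) should be read as an upper bound of the
pipeline's mechanics, not a field result.

## Problem sizes

Default study sizes, chosen for a single-CPU workstation run: 200
samples/class (1000 cubes) for the end-to-end recovery check, 60/class
for the PFE ablation at 5 dB SNR, three training seeds each, 50-seed
sweeps for trajectory-signature checks. The acceptance script uses
100/class for its main run and 60/class for the ablation.

## Known limitations

* Single point scatterer; no micro-Doppler limb structure.
* One RX channel; no angle information, so left/right discrimination
  rests entirely on excursion size and trend, not azimuth.
* The walk is piecewise-smooth (no gait bounce); DT maps lack the
  characteristic leg-swing striations.
* The adaptive threshold weight `a` is a constant per run, not chosen
  per map by an optimizer; "adaptive" refers to the map statistics
  entering P_th.
* Frame stitching ignores the inter-burst gap for Doppler bin spacing;
  STFT windows that a user configures to straddle burst boundaries
  (hop not dividing 128) will smear.
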
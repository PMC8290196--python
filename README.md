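# chronorsa

Temporal phenotyping of plant root system architecture (RSA) from
time-lapse images of seedlings growing on vertical agar plates.

Root phenotyping pipelines usually measure a plant once, at the end of
an experiment. When a camera photographs the same plate every 15
minutes instead, the root system becomes a *signal*: main-root (MR) and
lateral-root (LR) lengths become curves, growth speed becomes a time
series, and day/night physiology shows up as circadian (24 h) and
ultradian (12 h) oscillations in that series. `chronorsa` implements
the full computational chain needed to extract these temporal
phenotypes:

1. **Segmentation** — lightweight fully convolutional encoder–decoder
   networks (UNet, ResUNet, and a deeply supervised ResUNet) that
   classify every pixel as root or background. The networks run on a
   small self-contained numpy engine with reverse-mode automatic
   differentiation; no deep-learning framework is required. An
   ensemble mode averages the posterior maps of several members,
   P(y|x) ≈ (1/M) Σₘ P(y|x, θₘ).
2. **Refinement** — a fully connected CRF with a Potts compatibility
   and a bilateral appearance kernel (θ_α = 5 px, θ_β = 3 grey levels)
   homogenizes labels, and a temporal trailing average
   aᵗ = sᵗ + α aᵗ⁻¹ (α = 0.9) lets previous frames vote on the
   current one, so a water droplet that hides part of a root for a
   frame or two does not destroy the measurement.
3. **Graph reconstruction** — each plant mask is skeletonized and
   traversed depth-first from the seed (topmost root pixel); nodes are
   labelled seed / MR tip / bifurcation / LR tip, labels are tracked
   across frames by nearest-neighbour matching, and each frame is
   exported as an RSML document.
4. **Phenotypes** — MR/LR/TR length curves, LR count and density, MR
   fraction, dynamic convex-hull area, the MR-vs-ΣLR crossing time
   with the slope of the aligned difference curve (±24 h), growth
   speed, and Fourier energy of the speed signal at 1/24 h⁻¹ and
   1/12 h⁻¹, including a sliding 7-day-window energy series (672
   samples per window, so both target frequencies are exact DFT bins).

A seeded synthetic-root generator (`chronorsa.synthetic`) renders
growing root systems with exact ground-truth polylines and lengths, so
every stage is testable end to end without external data.

## Worked example

Simulate a seedling (MR at 0.3 mm/h, two laterals emerging at 10 h and
20 h), reconstruct the labelled graph for every frame, and read the
traits of the final frame:

```python
from chronorsa.synthetic import RootSystemSpec, simulate_root_system, render_mask
from chronorsa.rsa_graph import skeletonize_mask, graph_from_skeleton, label_roots
from chronorsa.phenotype import measure_frame

spec = RootSystemSpec(seed_position=(10, 150), mr_speed=0.3,
                      lr_emergence_times=(10.0, 20.0),
                      lr_angles=(45.0, -50.0), lr_speeds=(0.15, 0.13),
                      duration_h=48, image_size=(420, 320), mm_per_px=0.05,
                      rng_seed=1)
gt = simulate_root_system(spec)
prev = None
for frame in gt.frames:
    mask = render_mask(frame, spec)
    if not mask.any():
        continue
    g = label_roots(graph_from_skeleton(skeletonize_mask(mask),
                                        mm_per_px=0.05,
                                        timestamp_h=frame.time_h), prev)
    prev = g
print(measure_frame(g))
```

prints (values in mm, mm⁻¹, and dimensionless):

```
{'time_h': 48.0, 'mr_length_mm': 14.441, 'lr_total_length_mm': 10.62,
 'tr_length_mm': 25.062, 'lr_count': 2, 'lr_density_per_mm': 0.138,
 'mr_fraction': 0.576, 'tracking_failure': False}
```

against a ground truth of MR = 14.40 mm and LRs of 6.30 + 4.24 mm —
the reconstruction recovers every length to well within the
skeletonization bias. The spectral side:

```python
from chronorsa.synthetic import simulate_growth_signal
from chronorsa.phenotype import spectral_energy

_, speed = simulate_growth_signal(amp24=0.10, amp12=0.04, trend=0.3,
                                  noise_sd=0.01, duration_h=24 * 14,
                                  interval_h=0.25, rng_seed=1)
f = spectral_energy(speed[:-1])
print(f.energy_24, f.energy_12, f.amplitude(f.energy_24), f.amplitude(f.energy_12))
```

reports circadian/ultradian bin energies of 1134.1 and 187.4 and
recovers the injected oscillation amplitudes as 0.0995 and 0.0404 mm/h
(truth: 0.10 and 0.04).

The command line mirrors the library:

```sh
chronorsa simulate --spec myroot.yaml --out frames/
chronorsa run --config pipeline.yaml        # frames -> RSML + trait CSVs
chronorsa traits --graphs out/rsml --out traits.csv
chronorsa spectra --csv out/plant1_traits.csv
```

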
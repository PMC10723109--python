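# cztpet

Simulation and analysis toolkit for a four-panel small-animal PET prototype
built from 3-D position-sensitive CZT detectors. The detectors' sub-0.5-mm
spatial and ~1% energy resolution make multi-interaction (Compton) events
usable: the package models the full chain from photon transport to image,
including the Compton-kinematics machinery that identifies the first
interaction site and rejects chance coincidences.

It is aimed at detector/instrumentation researchers who want to study —
without hardware — how depth-of-interaction binning, Compton sequencing and
random rejection propagate into PET image quality.

## What is inside

* **Photon transport Monte Carlo** in CZT (Cd₀.₉Zn₀.₁Te): Klein–Nishina
  Compton scattering with impulse-approximation Doppler broadening
  (hydrogenic shell momentum profiles), photoelectric absorption, embedded
  attenuation tables, vectorised ray tracing through the 24 detector
  modules.
* **Detector response**: 1.9-mm anode-pixel merging, per-pixel trigger
  threshold, Gaussian energy blur (5.4 keV FWHM at 511 keV) and 0.5-mm 3-D
  position blur, 100-ns timing jitter, coincidence pairing with pile-up
  rejection — producing list-mode data (HDF5) with optional ground truth.
* **Analytic coincidence response and sensitivity**: for a source voxel i
  and detector-voxel pair (I₁, I₂) with D depth sublayers,

      p(A|i) = Σₙ Σₘ  [S₁cosφ/(4πd²) · e^(−µl) (1 − e^(−µl₀))]
                     · [S′/S₂ · e^(−µl′) (1 − e^(−µl₀′))]

  with S′ the back-projected slice overlap; the sensitivity map sums p(A|i)
  over all pairs (peak ≈ 2.2% at the FOV centre).
* **Near-field Compton response matrix** F(Ê₁, θ̂, d̂₂) from pencil-beam
  histories, its d̂₂-marginalised ("conventional") variant, and angular
  uncertainty maps.
* **Sequencing and rejection**: per-ordering relative probabilities
  F(i,j,k)/maxⱼF(i,·,k), threshold-based rejection, the false-rejection
  probability from F alone, and NECR′/NECR = (1 − p_fr)²/(1 − r) threshold
  optimisation.
* **Maximum-likelihood geometry calibration** of the 130-parameter setup
  from point-source scans (blur-aware LOR likelihood).
* **List-mode OS-EM** with DOI binning, decay-adjusted per-subset
  sensitivity, Gaussian post-filter, and the image metrics (profile FWHM,
  peak-to-valley ratio, normalised SD over ROIs).

See `docs/methods.md` for models, assumptions and defaults.

## Worked example

```python
import numpy as np
from cztpet import (SystemGeometry, PhantomSpec, make_phantom,
                    simulate_coincidences, build_response_matrix,
                    false_rejection_probability, sensitivity_at)
from cztpet.rejection import classify_events, reject_stream

geom = SystemGeometry.nominal()

# analytic sensitivity at the centre of the field of view
s = sensitivity_at(geom, [[0.0, 0.0, 0.0]], D=10, lateral_step=2)
print(f"peak sensitivity: {100 * s[0]:.2f} %")

# a short hot-rod acquisition at 25 uCi
rng = np.random.default_rng(7)
phantom = make_phantom(PhantomSpec("hot-rod"), 0.175)
data = simulate_coincidences(phantom, geom, duration=0.1, rng=rng)
cat, in_win = classify_events(data)
print(f"{data.n_events} coincidences, "
      f"{(cat == 0).sum()} single-single, "
      f"{np.isin(cat, (1, 2)).sum()} with a Compton side")

# near-field Compton response and random rejection at threshold 0.2
F = build_response_matrix(0, rng=rng, target_events=300_000)
stream = data.select(np.isin(cat, (1, 2)) & in_win)
accepted = reject_stream(stream, F, threshold=0.2)
print(f"false-rejection probability: "
      f"{false_rejection_probability(F, 0.2):.3f}")
print(f"accepted {accepted.sum()} of {stream.n_events} Compton events")
```

Output:

```
peak sensitivity: 2.18 %
2882 coincidences, 1468 single-single, 1142 with a Compton side
false-rejection probability: 0.109
accepted 280 of 377 Compton events
```

The 2.18% is the coincidence-response model's peak at the FOV centre; the
acquisition breaks down by interaction multiplicity (about half the
coincidences involve a Compton side); the false-rejection probability is the
fraction of *true* Compton coincidences the threshold-0.2 screen would
discard, computed from the response matrix alone; and most of this
(true-dominated) stream survives the screen.

A command-line layer wraps the same functionality:

```bash
cztpet demo --seed 1 --out runs/demo     # simulate -> response -> reject -> reconstruct -> metrics
cztpet simulate --phantom hot-rod --duration 0.2 --seed 1 --out runs/sim
cztpet reconstruct --listmode runs/sim/listmode.h5 --doi 1.0 --out runs/recon
```

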
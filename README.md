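# cfocus

Compressive Fourier-domain intensity masks for scattering correction in
two-photon microscopy — plus a physics-based virtual microscope to
generate, test and score corrections end to end.

## The problem

Deep in scattering tissue, the excitation focus of a two-photon microscope
degrades into speckle and the signal collapses.  One remedy modulates the
*intensity* of the pupil (Fourier) plane with a binary DMD mask: keep the
pupil superpixels whose fields arrive at the target in phase (they
interfere constructively, including multiply scattered paths), block the
rest.  To find that mask quickly, the target is excited with `n` random
binary patterns `A` (100×100 superpixels, 40 % on) while a PMT records the
fluorescence `I`, and the grayscale mask `x̂` is recovered from the
undersampled data by solving

    min_x  ‖I − A x‖²₂ + α·TV(x),    x ∈ [0, 1]^P

with FISTA (α = 0.008, ≤1000 iterations, fixed step 2×10⁻⁸, started from
the per-superpixel ON-minus-OFF contrast estimate), then binarized by
keeping the top superpixels at a 30 % output-to-input power ratio.
Compressive sensing with the TV prior means ~20–30 % of the fully sampled
measurement count suffices, and because the optical memory effect limits
each mask to an isoplanatic patch, the field of view is segmented into
content-aware subregions that each get their own mask.

This package implements the whole workflow — pattern generation,
acquisition (simulated or from recorded bundles), the solver, binarization
and power normalization, subregion segmentation, scanned-image synthesis,
and the metrology (enhancement fold, PSF FWHM/contrast, effective
attenuation length) — for simulation studies, algorithm development and
offline reprocessing of recorded DMD/PMT data.

## Worked example

```python
import numpy as np
from cfocus import (OpticalConfig, make_phase_screen, transfer_vector,
                    generate_random_patterns, pattern_signals,
                    compute_correction_mask, enhancement_from_transfer,
                    oracle_mask)

cfg = OpticalConfig.desk()                      # 32x32 superpixels, 256² grid
corr = 4 * cfg.superpixel_size * cfg.focal_pixel_pitch
medium = make_phase_screen(cfg, corr, phase_std=2.5, z_position=20.0, seed=1)

u = transfer_vector(medium, cfg)                # per-superpixel transmissions
patterns = generate_random_patterns(2000, cfg.superpixel_grid, 0.4, seed=11,
                                    superpixel_size=cfg.superpixel_size)
signals = pattern_signals(patterns, u)          # |A u|^4, noise-free

result = compute_correction_mask(patterns, signals, power_ratio=0.30)
print(f"on-count {result.binary.on_count}, "
      f"enhancement {enhancement_from_transfer(result.binary, u):.1f}x, "
      f"oracle {enhancement_from_transfer(oracle_mask(medium, cfg, power_ratio=0.30), u):.1f}x")
```

prints (seeds as above):

```
on-count 307, enhancement 31.4x, oracle 144.2x
```

meaning: binarization kept exactly 30 % of the 1024 superpixels; at equal
delivered power the corrected peak two-photon signal is 31.4× the
uncorrected (blank-mask) signal; a simulation-only oracle that selects the
truly most in-phase superpixels would reach 144× — the gap is the ranking
error of the compressive estimate at 2,000 measurements on this medium.

A thin CLI wraps the same library:

```
cfocus acquire --n-patterns 3000 --seed 5 --out bundle/
cfocus reconstruct --patterns bundle/patterns.tif \
    --measurements bundle/measurements.csv --power-ratio 0.30 --out recon/
cfocus segment --image uncorrected.tif --min-separation 20 --out sub.tif
cfocus sweep-measurements --counts 10,100,1000,10000 --out sweep.csv
```

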
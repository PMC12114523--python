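# caliberkit

Axon caliber morphometry for membrane-labeled fluorescence microscopy, with
a ground-truth phantom simulator for validation.

## The problem

In developing zebrafish larvae, the peripheral axons of Rohon–Beard (RB)
touch-sensory neurons arborize between two epithelial layers of the skin.
Their calibers span roughly 0.08–1.5 µm, vary along each segment
("pearling"), differ between sister branches, fluctuate on a timescale of
minutes, and respond to deformations of the surrounding skin cells — for
example when a basal cell rounds up for mitosis. Quantifying all of this
from super-resolution images of sparsely membrane-labeled neurons comes
down to one core measurement and a family of summary statistics built on
it, which this package implements as a tested, reusable pipeline:

- **Line-scan caliber.** A membrane label (e.g. EGFP-CAAX) renders an axon
  as two bright edges flanking a darker lumen. Caliber at a point is the
  distance between the two intensity peaks of a profile sampled
  perpendicular to the local axis: `c = x_right − x_left`, with sub-pixel
  peak localization and a below-resolution flag for unresolvable or
  too-small measurements (default limit 0.14 µm). A series in which more
  than 20% of measurements are flagged is excluded.
- **Branch metrics.** At a branch point, segment calibers are the mean of
  line scans 3, 4 and 5 µm from the branch (P = primary, S1/S2 = thicker /
  thinner secondary). Derived metrics: symmetry `S2/S1`, normalized
  calibers `S1/P`, `S2/P`, cross-sectional-area taper
  `(area_S1 + area_S2)/area_P` with `area = π(c/2)²`, and the pooled
  radius-scaling ratio `S/P`.
- **Dynamicity.** At a fixed location imaged at 5-min intervals, absolute
  dynamicity is the sample SD of caliber over frames and relative
  dynamicity is `%RSD = 100·SD/mean`; pearling of a lengthwise profile is
  the SD across 1 µm stations (excluding < 3 µm from branch points).
- **Dividing-cell analyses.** Station calibers grouped by the underlying
  cell territory {dividing, neighbor1, neighbor2}; border-to-border length
  of the axon across the dividing territory; the round → flat transition
  as the frame pair with the largest border-length increase; and a
  circular-arc path model `R = (ℓ²/4 + h²)/(2h)`,
  `arc = 2R·asin(ℓ/(2R))` for the axon's path over the rounded cell.
- **Statistics.** Paired sign-flip permutation test (exact 2ⁿ enumeration
  for n ≤ 20), Mann–Whitney U (tie-aware exact enumeration for
  n + m ≤ 14), paired mean difference with seeded BCa bootstrap 95% CI,
  and OLS regression R².

No imaging data ships with the package. Instead, `caliberkit.phantom`
renders seeded synthetic scenes — pearled membrane tubes (two boundary
curves at ±c(s)/2, Gaussian PSF, Poisson + read noise), four classes of
caliber dynamics (traveling pearl, focal inflation/deflation, segment
widening/narrowing, transient constriction), and a two-channel
dividing-cell scene — each with exported ground truth, so every stage of
the measurement pipeline is validated against known calibers.

## Worked example

```python
from caliberkit import (RunConfig, build_centerline, measure_lengthwise,
                        render_axon_image, straight_axon_spec)
from caliberkit.phantom import CaliberProfileSpec

profile = CaliberProfileSpec(0.25, pearls=((5.0, 0.35, 0.8), (11.0, 0.3, 1.0)))
spec = straight_axon_spec(16.0, profile, rng_seed=1)     # 0.04 µm/px phantom
stack, truth = render_axon_image(spec)

config = RunConfig()                                     # 1 µm stations
cl = build_centerline(spec.centerline_points_um)
series = measure_lengthwise(stack, cl, 0, config, anchors_s=[])
print(f"mean {series.mean():.3f} µm, pearling SD {series.pearling_sd():.3f} µm,"
      f" flagged {series.flagged_fraction():.0%}")
```

This prints

```
mean 0.336 µm, pearling SD 0.113 µm, flagged 0%
```

— the 17 stations average 0.34 µm because the two pearls (peaks ≈ 0.55–
0.60 µm) raise the 0.25 µm baseline, the pearling SD of 0.113 µm matches
the ground-truth SD of the generating profile at the same stations
(0.114 µm), and nothing fell below the 0.14 µm resolution limit.

The numbered drivers under `analysis/` run the full studies and write
their tables under `results/`:

```bash
python analysis/01_simulate_scenes.py   # phantom scenes + ground truth
python analysis/02_measure_calibers.py  # recovery accuracy by true caliber
python analysis/03_branch_metrics.py    # symmetry / taper / radius scaling
python analysis/04_dynamics.py          # %RSD recovery, events, day pairing
python analysis/05_dividing_cell.py     # territory comparison, round/flat
python analysis/06_full_pipeline.py     # everything, one command
```

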
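# cprnfl

Circumpapillary retinal nerve fiber layer (cpRNFL) thickness profiling and
reliability analysis for hand-held OCT raster volumes, with a synthetic
retinal phantom generator.

The RNFL — the layer of ganglion-cell axons converging on the optic nerve
head (ONH) — thins in glaucoma and other optic neuropathies, and its
thickness along a circle around the ONH is the standard structural marker.
In infants and young children, imaged awake with a hand-held OCT probe,
the measurement chain differs from table-mounted devices: volumes come as
anisotropic rasters (e.g. 12 mm × 8 mm, 600 A-scans × 80 B-scans, so 20 µm ×
100 µm sampling), the ONH is centred manually, and radii are best expressed
as *visual angles* (288 µm/degree in the adult eye; 6° ≈ 1.73 mm), which
sidesteps axial-length growth corrections. This package implements that
measurement chain and the statistics used to qualify it:

* **geometry** — visual-angle calibration, window cropping, and polar
  resampling (bilinear, in physical mm coordinates) of thickness maps onto
  rings (4°, 5°, 6°) and area-weighted annuli (4–5°, 5–6°), with TSNIT
  quadrant partitions (equal 90° sectors, or GDx-style unequal sectors) and
  left-eye mirroring.
* **extraction** — per-(location × quadrant) mean thickness with capture
  flags, the "≥ 3 quadrants captured in both scans (the same three)"
  pair-inclusion rule, and the Average measure for fully captured eyes.
* **reliability** — ICC(A,1)/(C,1) from the two-way ANOVA mean squares with
  F-based 95% CIs, within-subject CoV (100·S_w/mean, S_w = √(Σdᵢ²/2n)),
  bias with t-based CI and p (≡ paired t-test for two complete arms), and
  Bland–Altman limits of agreement with the difference-vs-mean trend.
* **feasibility** — attempted/imageable bookkeeping with per-factor
  exclusions, per-quadrant success rates on "possible" and "attempted"
  bases, integer count reconstruction from printed percentages, and pooling.
* **phantom** — a synthetic cohort generator: an analytic double-hump RNFL
  field (superior/inferior bundles ≈ 106/105 µm over a temporal/nasal
  baseline ≈ 61/65 µm at 6°), glaucomatous global thinning, and a
  variance-component error model (subject / scan / assessor offsets +
  quality-dependent pixel noise, tilt, missing quadrants), so the entire
  pipeline can be exercised and validated without patient data.

Intended users: researchers developing or validating pediatric OCT analysis
pipelines, and anyone needing a self-contained test-retest/interassessor
agreement toolkit for paired thickness measurements.

## Worked example

Simulate a 51-subject test–retest cohort (two consecutive scans per
subject, high/low quality), crop to the 8 mm × 8 mm analysis window, sample
the 6° ring, and compute the per-quadrant agreement table:

```python
import pandas as pd
from cprnfl import (PhantomParams, simulate_cohort, crop_to_window,
                    summarize_scan, summaries_to_frame, build_pairs,
                    reliability_table, results_to_frame)

params = PhantomParams(seed=1)                      # control cohort, default error model
scans = simulate_cohort(params, n_subjects=51)      # 51 subjects x 2 consecutive scans
arm = lambda s: "high_quality" if s.scan_id == "scan1" else "low_quality"
table = pd.concat(
    [summaries_to_frame(summarize_scan(crop_to_window(s, (8.0, 8.0))), arm_of=arm)
     for s in scans], ignore_index=True)
pairs = build_pairs(table, ("high_quality", "low_quality"))
results = reliability_table(pairs, locations=["ring6"])
cols = ["quadrant", "n", "mean_a_um", "mean_b_um", "bias_um", "bias_p",
        "cov_percent", "icc", "icc_lci", "icc_uci"]
print(results_to_frame(results)[cols].round(2).to_string(index=False))
```

prints

```
quadrant  n  mean_a_um  mean_b_um  bias_um  bias_p  cov_percent  icc  icc_lci  icc_uci
   nasal 51      66.19      65.53     0.66    0.39         5.81 0.90     0.83     0.94
temporal 51      62.04      61.47     0.56    0.45         6.06 0.91     0.84     0.95
inferior 49     105.47     104.86     0.61    0.40         3.40 0.92     0.86     0.95
superior 51     107.37     106.12     1.25    0.09         3.52 0.90     0.84     0.94
 Average 49      85.24      84.49     0.75    0.30         4.17 0.92     0.86     0.95
```

Each row is one quadrant (plus the four-quadrant Average) at the 6° ring:
the two arms' mean thickness (µm), the systematic difference between them
with its paired-t p-value, the within-subject CoV (%), and the
absolute-agreement ICC with its 95% CI. `n` drops below 51 where a scan
lost a quadrant (the inclusion rule keeps the subject for the remaining
quadrants, but the Average needs all four). Note inferior/superior ≈
105–107 µm vs temporal/nasal ≈ 61–66 µm — the double-hump profile — and
ICCs near 0.9, set by the generator's subject/scan variance components.

The same pipeline is scriptable from the shell:

```sh
cprnfl simulate --n-subjects 51 --design test_retest --seed 1 --out-dir scans/
cprnfl extract scans/ --out measurements.csv
cprnfl reliability measurements.csv --design test_retest \
       --out reliability.csv --sweep-out icc_by_location.csv
cprnfl feasibility src/cprnfl/data/example_feasibility.json --out feasibility.csv
```

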
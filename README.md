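# accell — automated anterior-chamber cell analysis for anterior-segment OCT

In uveitis, hyphema and post-surgical inflammation, blood cells appear in the
normally clear anterior chamber (AC) of the eye.  Clinically they are graded
at the slit lamp with the SUN scale (0+ to 4+), which is subjective,
non-quantitative and coarse.  On an anterior-segment SD-OCT B-scan the same
cells are visible directly as small hyperreflective specks in the dark
aqueous below the bright corneal band, so they can be counted by software.

`accell` is a library + CLI that quantifies those cells fully automatically
in 8-bit grayscale B-scans (BMP/PNG), for ophthalmic imaging researchers who
want objective per-image cell densities and cell-shape statistics.  Because
OCT exposure, noise and artifacts vary strongly between images, every
threshold is re-derived per image:

1. **Corneal segmentation.**  The global intensity histogram of the
   median-blurred image is bimodal — a dark lobe (air + aqueous + speckle)
   and a bright lobe (cornea, iris, artifacts).  The corneal cutoff is the
   valley of an 11-bin moving average between the two lobe peaks.
   Thresholding the original image at the cutoff and taking per-column
   envelopes of the corneal band partitions the scan into air / cornea /
   anterior chamber.
2. **Artifact masking.**  A 21×21 median filter preserves wide bright
   structures (cornea, iris, broad artifacts) and erases small specks, so
   thresholding the filtered image masks everything that cannot be a cell; a
   3×3 median separates compact specks from single-pixel shot noise.  Any
   image column with ≥ 16 candidate pixels is treated as a vertical
   reflection line and cleared.
3. **Noise floor.**  Air contains no scatterers, so its recorded signal is
   pure noise — right-skewed and non-Gaussian, which defeats mean + 2·SD
   rules.  The per-image detection threshold is the nonparametric 99.5th
   percentile (nearest rank) of the air pixels.
4. **Cells.**  8-connected components of chamber pixels above the noise
   floor (≥ 2 px) are cells.  Per cell, the boundary polygon through the
   outermost pixel centres gives area *S* and perimeter *L*; modelling the
   cell as an ellipse with semi-axes *a* ≤ *b*,

   *S* = π·a·b,  *L* ≈ 2π·√((a² + b²)/2),

   the eccentricity e = √(1 − a²/b²) follows in closed form:

   e = √(1 − [L⁴ − 8π²S² − L²√(L⁴ − 16π²S²)] / (8π²S²)).

   Cells of < 3 px are excluded from eccentricity statistics (pixelation
   overestimates their perimeter, hence their e).  Per image, cell density =
   cells per 10⁶ chamber pixels.

A phantom generator (`accell.phantom`) renders OCT-like scans — curved
corneal band, iris with pupil gap, skewed speckle noise, reflection lines,
ghost blobs, planted elliptical cells — with exact ground truth, so the
entire pipeline is testable without patient data.

## Worked example

```bash
accell synth   --output demo/scans --n-scans 3 --n-cells 25 --seed 4
accell analyze --input demo/scans --output demo/results \
               --metadata demo/scans/metadata.csv --overlay
accell evaluate --input demo/scans --truth demo/scans --output demo/eval
```

prints (log lines are per-image; numbers are produced by the run):

```
wrote 3 phantom scans to demo/scans
INFO:accell:scan phantom-000: cutoff=92 (valley) noise=111 area=116238 cells=25 density=215.08 qc=ok
INFO:accell:scan phantom-001: cutoff=90 (valley) noise=107 area=116256 cells=24 density=206.44 qc=ok
INFO:accell:scan phantom-002: cutoff=64 (valley) noise=112 area=116221 cells=24 density=206.50 qc=ok
analyzed 3 scans (0 unanalyzable); results in demo/results
mean recall 0.973, mean precision 1.000 over 3 scans; details in demo/eval/recovery.csv
```

Per scan: `cutoff` is the histogram-valley corneal threshold, `noise` the
99.5th-percentile air noise floor, `area` the chamber size in pixels,
`density` the cell count per million chamber pixels.  The 25 planted cells
of scan `phantom-000` are recovered exactly; `evaluate` confirms 97% recall
and no false detections against the generator's ground truth.
`demo/results/scans.csv` holds one row per image:

```
scan_id,slice_index,qc_status,corneal_cutoff,noise_threshold,ac_area_px,cell_count,density_per_1e6px,mean_eccentricity,grade_label,diagnosis_label
phantom-000,0,ok,92,111,116238,25,215.07596483077825,0.8667759476474345,,
```

and `cells.csv` one row per detected cell (centroid, pixel count, *S*, *L*,
e).  Mean eccentricities of small roundish cells sit around 0.86 — high, not
near 0 — because pixelated boundaries carry a perimeter excess; the value is
still discriminative between cell shapes, which is why it is reported.
Scans whose air/cornea/chamber decomposition fails (e.g. flat dark images)
are reported with `qc_status=unanalyzable` rather than aborting the batch.

The library mirrors the CLI: `read_scan`, `process_scan`, `process_batch`,
`aggregate_by_group` (per-grade / per-slice / per-diagnosis summary tables
on which standard statistical tests can be run), and `generate_scan` /
`generate_cohort` for phantoms.

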
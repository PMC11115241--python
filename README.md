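# hybridct

Simulation and analysis toolkit for **hybrid photon-counting / energy-integrating
micro-CT** of iodine-stained specimens.

Ex vivo micro-CT of Lugol-stained mouse brains in PBS-filled vials can match
MRI for regional morphometry at a fraction of the scan time, but the imaging
chain has two characteristic artifacts: multi-tile photon-counting detectors
(PCDs) have tile-to-tile spectral response mismatch that produces concentric
ring/band artifacts, and energy-integrating detectors (EIDs) suffer
beam-hardening cupping. This package implements the full computational
pipeline that addresses both — entirely on synthetic phantoms, so every stage
is testable without scan data:

- **Spectral simulation** (`hybridct.spectra`, `hybridct.phantoms`,
  `hybridct.simulate`): polychromatic Beer–Lambert forward projection of
  voxelized material phantoms (water, iodine with its 33.17 keV K-edge,
  acrylic, aluminum, calcium) through a 2-threshold, 8-tile PCD and an EID
  chain, with per-tile threshold offsets/gains, Poisson noise and flat
  fields.
- **Projection corrections** (`hybridct.corrections`): the multiplicative
  PBS gain-ratio correction for tile artifacts (ideal-vial reconstruction,
  forward projection, 4×4-median-filtered count-domain ratio, out-of-vial
  column replacement) and the per-detector-row 2nd-degree polynomial
  beam-hardening correction calibrated on acrylic/aluminum plate scans.
- **Reconstruction** (`hybridct.recon`): filtered backprojection with a
  Ram-Lak filter, and the hybrid multi-channel iterative reconstruction

  ```
  X^ = argmin_X  1/2 Σ_e ||R X(e) − Y(e)||²  +  λ ||X||_BTV
  ```

  solved by split Bregman with the add-residual-back strategy (4 outer
  iterations), a conjugate-gradient data step, and joint bilateral-total-
  variation denoising whose edge weights and low-rank channel coupling are
  shared across energies — so the ring-free EID channel suppresses residual
  PCD tile rings.
- **Material decomposition** (`hybridct.decompose`): per-voxel water/iodine
  inversion `C = X M⁻¹` with a vial-calibrated sensitivity matrix and
  non-negativity by projection onto the material cone.
- **Image quality** (`hybridct.quality`): line-profile fits with r², percent
  image uniformity `PIU = 100(1−(max−min)/(max+min))`, CNR
  `(μ₁−μ₂)/√((σ₁²+σ₂²)/2)`, CV `σ/μ`, HU conversion/linearity, and
  bar-pattern MTF with Gaussian fit and the 10 %-MTF resolution `f10`.
- **Morphometry statistics** (`hybridct.morphometry`): per-region volumes as
  percent of total, pooled-variance two-sample t-tests with
  Benjamini–Hochberg FDR at 5 %, Cohen's d, 95 % CIs, percent differences,
  and one-way ANOVA of total volume.

## Worked example

Simulate a stained-brain-in-PBS-vial study at desk scale, apply both
corrections, reconstruct, and measure uniformity:

```python
from hybridct.pipeline import brain_study, central_profile
from hybridct.quality import piu
from hybridct.corrections import band_artifact_score

res = brain_study(seed=1)
for ch in ("PCD15", "PCD34", "EID"):
    print(ch, f"PIU = {piu(central_profile(res['hybrid_recon'], ch)):.2f} %")
mask = res["gain_ratio"].column_mask
print("band artifact, PCD15:",
      f"{band_artifact_score(res['pcd_scan'], 'PCD15', column_mask=mask):.5f}",
      "->",
      f"{band_artifact_score(res['pcd_corrected'], 'PCD15', column_mask=mask):.5f}")
```

Output (about a minute on one CPU):

```
PCD15 PIU = 94.03 %
PCD34 PIU = 88.93 %
EID PIU = 93.89 %
band artifact, PCD15: 0.03292 -> 0.00203
```

The central line profile through the corrected, hybrid-reconstructed vial is
uniform to within ~6 % (PIU ≥ 88 % in every channel), and the tile-gain
correction cuts the projection-domain band-artifact score by ~16×. Without
the correction the 15 keV PIU drops below 50 %.

The same workflows are available from the shell:

```bash
hybridct simulate --phantom brain --seed 1 --out study/
hybridct correct --scan study/projections --pbs-scan pbs/projections \
    --apply-bh --out corrected/
hybridct recon --proj corrected/ --method hybrid-iterative --out vol.nii.gz
hybridct decompose --recon vol.nii.gz --labels vials_labels.nii.gz \
    --concs 9.25,4.625,2.3125,1.1563 --out-iodine I.nii.gz --out-water W.nii.gz
hybridct morpho --labels labels/ --groups groups.csv --compare sex:F:M \
    --out stats.csv
```

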
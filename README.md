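# choroid3d

Three-dimensional quantification of the choroidal vasculature from
swept-source OCT (SS-OCT) volumes.

The choroid — the vascular layer between retina and sclera — remodels in
age-related macular degeneration and other chorioretinal disease. Given an
8-bit SS-OCT volume (e.g. a 12 × 12 mm wide-field scan of 1024 B-scans at
1024 × 1536) together with the choroid's inner (RPE–choriocapillaris) and
outer (chorioscleral) boundary surfaces, `choroid3d` segments the vessel
lumens in 3D and reports, per macular sector and for the whole field:

- **MChVD** — mean choroidal vessel diameter: for each sector's three largest
  vessels (representative diameter > 100 µm, the Haller-vessel floor), three
  cross-sectional diameters are measured along the centerline; MChVD is the
  mean of the nine site values.
- **IVD** — inter-vessel distance: for each of the same nine sites, the
  minimum edge-to-edge distance from the vessel surface near the site to the
  nearest other vessel in the sector; the sector IVD is the mean of the nine.
- **ChT** — choroidal thickness `(z_o − z_i)·dz` in µm.
- **CVI** — choroidal vascularity index: luminal volume / total choroidal
  volume (an exact voxel-count ratio).

Sectors follow the ophthalmic convention: a central circle of 4 mm diameter
around the fovea plus nasal/temporal/superior/inferior quadrants delimited by
the 45° diagonals; optic-disc columns are excluded everywhere.

Vessel segmentation uses Phansalkar local adaptive thresholding per B-scan
within the choroid slab,

&nbsp;&nbsp;&nbsp;&nbsp;`t = m · (1 + p·e^(−q·m) + k·(s/r − 1))`,

with window statistics over 16 × 16 px tiles (or a per-pixel sliding window),
followed by 3D morphological cleanup. Vessel geometry is measured on the
anisotropic Euclidean distance transform along a ridge-following medial
centerline, all in physical µm. A reliability module provides the
two-way random, single-measurement, absolute-agreement ICC with its F-based
95% CI and the standard interpretation bands (0.5 / 0.75 / 0.9).

Because no patient scans ship with the package, a first-class phantom
generator produces synthetic scans with exact ground truth (designed
diameters, inter-vessel gaps, luminal fraction, slab thickness), so every
stage is validated by parameter recovery.

## Worked example

Simulate a phantom with three vessels of designed diameter 150/200/250 µm in
a 440 µm slab, run the full pipeline on it, and compare against ground truth:

```python
import choroid3d as c3

spec = c3.PhantomSpec(
    grid_shape=(100, 200, 160), spacing=(12.0, 12.0, 4.0),
    inner_depth=100.0, choroid_thickness=440.0,
    vessels=tuple(
        c3.straight_tube(300.0 + 400.0 * i, 300.0, d, 200.0, 2200.0)
        for i, d in enumerate((150.0, 200.0, 250.0))
    ),
)
cfg = c3.PipelineConfig(out_dir="scratch/demo", central_diameter_um=100000.0)
report = c3.simulate_and_validate(spec, cfg)
print(report.to_string(index=False))
```

prints

```
metric  sector      truth   estimate     error
   cvi average   0.162827   0.159425 -0.003402
cht_um average 440.000000 440.000000  0.000000
```

i.e. the designed luminal fraction (16.3%) is recovered to three decimal
places through binarization and the flat slab thickness is exact. The
per-sector table written to `scratch/demo/run/metrics.csv` holds one row per
sector plus an `average` row; here all three vessels fall into the (enlarged)
central sector, whose MChVD of ≈184 µm sits within one voxel diagonal plus
discretization bias of the designed 200 µm mean, with all nine diameter and
nine IVD sites retained in `sites_audit.csv` for audit.

The same workflow is available from the shell:

```bash
choroid3d simulate phantom.yaml --out scratch/ph
choroid3d run config.yaml
choroid3d icc ratings.csv
```

## Layout

- `src/choroid3d/phantom.py` — synthetic scan generator with exact ground truth
- `src/choroid3d/volume_io.py` — volumes, masks and tables (TIFF/PNG/IMG/CSV)
- `src/choroid3d/choroid_geometry.py` — boundary surfaces, smoothing, slab mask, ChT
- `src/choroid3d/binarize.py` — Phansalkar thresholding and morphological cleanup
- `src/choroid3d/sectors.py` — fovea-centered five-sector grid, fovea localization
- `src/choroid3d/metrology.py` — centerlines, diameters, selection, IVD
- `src/choroid3d/metrics.py` — CVI, table assembly, absolute-agreement ICC
- `src/choroid3d/pipeline.py`, `cli.py` — batch orchestration and CLI

See `docs/methods.md` for the models, parameter choices and limitations.
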
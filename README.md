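# fishstrat

Quantitative analysis of three-dimensional population stratification in
moving-bed biofilm reactor (MBBR) carrier biofilms from fluorescence *in
situ* hybridization (FISH) cryosection micrographs.

In nitritation-anammox MBBRs, aerobic ammonia-oxidizing bacteria (AOB) and
anaerobic ammonium-oxidizing (anammox) bacteria share ~1 mm square carrier
compartments. Cryosectioning the biofilm parallel to the carrier face yields
one multi-channel micrograph per depth z: a reference channel for all
bacteria (probe mix EUB338mix) plus specific channels for AOB (Nse1472) and
anammox (Bfu613). `fishstrat` turns such section stacks into quantitative
stratification profiles:

- **Preprocessing** — fixed-cutoff or gradient-weighted (RATS) intensity
  thresholding, single-pass speckle noise reduction (minimum non-zero
  8-neighbors), area-mean reduction of oversized images to 1 megapixel, and
  assembly of microscope tiles into wall-to-wall compartment images.
- **Objects & biovolume** — 8-connected segmentation of probe-labeled
  biomass; per-object *congruency* c = |object ∩ reference| / |object|;
  removal of autofluorescent objects present in both specific channels
  (≥50% mutual overlap); congruency-based artifact rejection (drop objects
  with c < 0.50, flag images whose kept-area congruency is < 0.90); biovolume
  fraction = kept specific area / reference area.
- **Slicer** — every compartment pixel is labeled by Euclidean distance to
  the compartment wall and binned into concentric 100 µm virtual slices;
  per-slice biovolume fractions are averaged across sections with t-based
  95% confidence intervals.
- **Geometry** — compartment side/diagonal measurement via the minimal-area
  bounding quadrilateral, shrinkage ratios against carrier dimensions, and
  eight biofilm-thickness readings (four side-normal, four corner-diagonal)
  with skipping of narrow biofilm channels.
- **Depth statistics** — ordinary least squares of fraction on depth, with
  R², n, and a two-sided slope t-test at level α, over explicit depth
  windows.
- **Stoichiometry** — hydraulic retention time, nitrogen removal and
  nitrate-to-ammonium-removal percentages, the stoichiometric nitrate
  fraction of combined nitritation-anammox
  (0.26 / (1 + 1.32) ≈ 11%), and carrier depth-coverage arithmetic.
- **Synthetic generator** — FISH-like section stacks with pixel-exact ground
  truth (class masks, planted artifacts, speckle), used to validate every
  stage end to end.

## Worked example

Generate a synthetic 17-section stack with planted stratification (AOB
declining 0.40 → 0.05 over 0–800 µm, anammox rising 0 → 0.30 over
180–400 µm, higher near the walls), then run the full pipeline:

```python
from fishstrat.synthetic import SyntheticConfig, generate_compartment_stack, save_stack
from fishstrat.pipeline import PipelineConfig, run_pipeline

cfg = SyntheticConfig(grid_size_px=250, pixel_size_um=2.0,
                      compartment_side_um=500.0,
                      section_depths_um=tuple(range(0, 801, 50)),
                      speckle_rate=0.5, artifact_rate=5.0, seed=1)
images, gt = generate_compartment_stack(cfg)
manifest = save_stack(images, gt, "demo_stack")

pcfg = PipelineConfig(
    sections=[{"path": r.path, "depth_um": r.depth_um} for r in manifest.itertuples()],
    out_dir="demo_out",
    regression_windows={"aob": None, "amx": (180.0, 400.0)},
    alpha=0.01,
)
results = run_pipeline(pcfg)
for probe, res in results["regressions"].items():
    print(res.summary())
```

prints

```
aob: slope -4.204e-04 per um over 0-800 um, R2 = 0.96, n = 17, p = 9.83e-12 (significant at alpha = 0.01)
amx: slope 1.390e-03 per um over 180-400 um, R2 = 0.99, n = 5, p = 7.10e-04 (significant at alpha = 0.01)
```

i.e. the AOB biovolume fraction falls significantly with depth (slope
−4.2 × 10⁻⁴ per µm, R² = 0.96 across 17 sections) while the anammox
fraction rises significantly inside the 180–400 µm window — the planted
stratification, recovered from the rendered images. `demo_out/` additionally
holds per-object tables, the depth profile, per-shell ("slicer") profiles
with confidence intervals, geometry/thickness tables and a run log. The
same steps are available from the shell:

```sh
fishstrat generate --out-dir demo_stack --seed 1 --n-sections 17
fishstrat run --config run.yaml
fishstrat stoich --influent-nh4 314 --effluent-nh4 71 --effluent-no2 14 --effluent-no3 25
```

The last command reports `HRT: 6.3 h`, the stoichiometric nitrate ratio of
`11%`, and the nitrogen balance of the given reactor record (N removal
64.97%, nitrate production / ammonium removal 10.29%).

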
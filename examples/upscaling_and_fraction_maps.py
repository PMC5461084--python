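"""Multi-resolution assessment via spectral aggregation and fraction maps.

Coarser pixels are simulated by block-averaging the spectra; the matching
reference map comes from the fine-resolution truth as a target-fraction
map thresholded by the strict majority rule (> 0.5). The pipeline is then
rerun at each scale.
"""

import svddmap as sm

spec = sm.canonical_scene_spec(seed=5)
raster, truth = sm.generate_scene(spec)
code = spec.target_index

res = sm.run_oneclass_mapping(raster, truth.labels, code, seed=5)
print(f"factor 1 (native): OA = {res.report.OA:.1%}  PA = {res.report.PA:.1%}  "
      f"UA = {res.report.UA:.1%}")

for factor in (2, 4):
    coarse = sm.aggregate_raster(raster, factor)
    frac = sm.fraction_map(truth.labels, code, factor)
    ref = sm.majority_labels(frac)  # 1 = target where fraction > 0.5
    result = sm.run_oneclass_mapping(coarse, ref, target_code=1, seed=5)
    rep = result.report
    print(f"factor {factor} ({coarse.height}x{coarse.width} px): "
          f"OA = {rep.OA:.1%}  PA = {rep.PA:.1%}  UA = {rep.UA:.1%}")

print("\nAggregation homogenizes the target's spectra, so the hypersphere "
      "covers them\nmore easily; boundary mixing moves into the coarse pixels "
      "instead, which the\nmajority-rule reference absorbs.")
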
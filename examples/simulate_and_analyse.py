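"""Generate a small synthetic cohort and run the full pipeline on it.

Builds one bulk-staining (I2KI-like) and one front-staining (PTA-like)
phantom series with known ground truth, writes them as TIFF slices, and
runs profile extraction, edge/front detection, kinetics fits, shrinkage
morphometry and the day x stain statistics in one call.
"""

import tempfile
from pathlib import Path

from ctstain import PhantomSpec, PipelineConfig, generate_cohort, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="ctstain_demo_"))
specs = [
    PhantomSpec(mode="saturating", radius0_mm=1.2, I0=0.1, Imax=0.6,
                k0=1.0, c_k=0.3, noise_sigma=0.01, seed=1,
                stain="I2KI", sample_id="lig1", shrink_fraction=0.05),
    PhantomSpec(mode="front", radius0_mm=1.2, C=1.1, K=0.5,
                front_width_mm=0.2, noise_sigma=0.01, seed=2,
                stain="PTA", sample_id="lig2", shrink_fraction=0.11),
]
manifest = generate_cohort(specs, workdir / "cohort")
print(f"cohort written to {manifest.parent}")

cfg = PipelineConfig(manifest=str(manifest), output_dir=str(workdir / "out"),
                     max_depth_mm=1.0, reference_depth_mm=0.5)
res = run_pipeline(cfg)

print("\nDetected stain fronts (mean depth per day, PTA sample):")
pta = res.front_table.query("stain == 'PTA' and found")
print(pta.groupby("day")["depth_mm"].mean().round(3))
# depths increase day by day and level off as the front saturates

if "PTA" in res.front_models:
    m = res.front_models["PTA"]
    print(f"\nfitted front model: C = {m.C:.2f} mm (true 1.1), "
          f"K = {m.K:.2f}/day (true 0.5)")

print("\nNormalised cross-sectional areas (shrinkage):")
print(res.area_table.pivot_table(index="day", columns="stain",
                                 values="normalized_area").round(3))
# the PTA-like sample loses ~2x more area than the I2KI-like one
print(f"\nall outputs under {res.output_dir}")
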
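"""Generate the synthetic study inputs: fiber fields across concentration
levels, a registered H&E/SHG pair, IHC slides, and training/validation
survival cohorts.  Everything downstream (scripts 02-05) reads from
results/data/.

Ground truth is written next to every artifact so each later stage can be
scored against what was actually drawn.
"""

import json
import math
from pathlib import Path

import numpy as np
import tifffile

from collalign import (
    AffineTransform,
    CohortSpec,
    FiberFieldSpec,
    make_cohort,
    make_fiber_image,
    make_he_pair,
    make_ihc_image,
)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# --- fiber fields across orientation concentrations -----------------------
kappas = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
for i, kappa in enumerate(kappas):
    spec = FiberFieldSpec(
        n_fibers=300, mean_angle=40.0, kappa=kappa, image_size_px=(384, 384), seed=SEED + i
    )
    img, fibers = make_fiber_image(spec)
    tifffile.imwrite(OUT / f"fibers_kappa{kappa:g}.tif", img.astype(np.float32))
    fibers.to_dataframe().to_csv(OUT / f"fibers_kappa{kappa:g}_truth.csv", index=False)
print(f"wrote {len(kappas)} fiber fields (kappa = {kappas})")

# --- H&E / SHG pair with a known affine map --------------------------------
spec = FiberFieldSpec(
    n_fibers=220, mean_angle=130.0, kappa=3.0, image_size_px=(256, 256), seed=SEED + 7
)
shg, fibers = make_fiber_image(spec)
true_t = AffineTransform.rotation(4.0, center=(128, 128)).compose(
    AffineTransform.translation(8.0, -5.0)
)
pair = make_he_pair(shg, fibers, true_t, seed=SEED + 8)
tifffile.imwrite(OUT / "shg.tif", shg.astype(np.float32))
tifffile.imwrite(OUT / "he.tif", pair.rgb)
true_t.to_json(OUT / "he_to_shg_true.json", note="ground-truth moving->fixed map")
print("wrote H&E/SHG pair with known transform (rotation 4 deg + translation (8, -5))")

# --- IHC slides with exact positivity --------------------------------------
fractions = [0.05, 0.30, 0.60]
truths = {}
for j, f in enumerate(fractions):
    ihc = make_ihc_image(f, seed=SEED * 10 + j)
    tifffile.imwrite(OUT / f"ihc_{int(100 * f)}.tif", ihc.rgb)
    truths[f"ihc_{int(100 * f)}"] = ihc.true_fraction
(OUT / "ihc_truth.json").write_text(json.dumps(truths, indent=2))
print(f"wrote {len(fractions)} IHC slides, true fractions {list(truths.values())}")

# --- cohorts ----------------------------------------------------------------
train = make_cohort(CohortSpec(n_patients=70, seed=SEED + 101))
train.write_csv(OUT / "train_patients.csv", OUT / "train_rois.csv")
cohort = make_cohort(CohortSpec(n_patients=114, seed=SEED + 202))
cohort.write_csv(OUT / "cohort_patients.csv", OUT / "cohort_rois.csv")
print(
    "wrote training (n=70) and validation (n=114) cohorts: "
    f"{int(cohort.patients['high_true'].sum())} high-alignment patients, "
    f"HR {math.exp(cohort.spec.log_hr_alignment):.2f}, "
    f"{1 - cohort.patients['event'].mean():.0%} censored"
)
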
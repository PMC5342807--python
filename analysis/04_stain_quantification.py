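"""Score the simulated IHC slides: color-deconvolved DAB positivity
against the generator's exact fractions, ordinal stromal scores, and an
EMT double-positivity example.

Finding: measured positivity agrees with the drawn fraction to ~0.01
(8-bit quantization is the only error source), and the ordinal scale bins
the three slides as low / moderate / high.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from collalign import (
    StainModel,
    average_scores,
    color_deconvolve,
    emt_double_positive_fraction,
    positivity_fraction,
    rgb_to_od,
    stromal_score,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
TABLES = ROOT / "tables"
TABLES.mkdir(parents=True, exist_ok=True)

truths = json.loads((DATA / "ihc_truth.json").read_text())
sm = StainModel.h_dab()
rows = []
for name, true_frac in truths.items():
    rgb = tifffile.imread(DATA / f"{name}.tif")
    conc, n_clipped = color_deconvolve(rgb_to_od(rgb.astype(float)), sm)
    res = positivity_fraction(conc[..., 1], conc[..., 0])
    rows.append(
        {
            "slide": name,
            "true_fraction": round(true_frac, 4),
            "measured_fraction": round(res.fraction, 4),
            "abs_error": round(abs(res.fraction - true_frac), 4),
            "n_dab_px": res.n_dab,
            "n_hematoxylin_px": res.n_hematoxylin,
            "clipped_px": n_clipped,
            "stromal_score": stromal_score(res.fraction),
        }
    )
df = pd.DataFrame(rows)
df.to_csv(TABLES / "positivity.csv", index=False)
print(df.to_string(index=False))

# two blinded reviewers scoring the middle slide one bin apart
print(f"\nreviewer-averaged stromal score example: {average_scores([2, 3])}")

# per-cell EMT scoring on a constructed table: 30 of 150 epithelial cells
# co-express both markers above threshold
rng = np.random.default_rng(0)
n, n_double = 150, 30
cells = pd.DataFrame(
    {
        "cell_id": np.arange(n),
        "ecadherin": np.full(n, 1.0),
        "vimentin": np.where(np.arange(n) < n_double, 1.0, 0.1),
        "epithelial": True,
    }
)
emt = emt_double_positive_fraction(cells, thr1=0.5, thr2=0.5)
print(f"EMT double-positive fraction: {emt:.3f} (constructed truth {n_double / n:.3f})")
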
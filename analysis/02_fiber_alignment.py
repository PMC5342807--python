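"""Quantify collagen alignment in the simulated fiber fields and compare
the measured mean resultant length against the generator's ground truth.

Finding: measured R increases monotonically with the von Mises
concentration and tracks the true R of the drawn angles within a few
hundredths at moderate-to-high concentration; in near-isotropic fields the
finite number of extracted segments biases R upward by ~0.05-0.1, the
familiar small-sample inflation of resultant-length estimates.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from collalign import ROI, alignment_score, roi_alignment

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
TABLES = ROOT / "tables"
TABLES.mkdir(parents=True, exist_ok=True)

rows = []
for tif in sorted(DATA.glob("fibers_kappa*.tif")):
    kappa = float(tif.stem.replace("fibers_kappa", ""))
    img = tifffile.imread(tif)
    truth = pd.read_csv(DATA / f"{tif.stem}_truth.csv")
    r_true = alignment_score(truth["theta_deg"].to_numpy())
    res = roi_alignment(
        img, ROI(x=42, y=42, side_px=300, roi_id=tif.stem), min_length_px=15
    )
    rows.append(
        {
            "kappa": kappa,
            "n_fibers_drawn": len(truth),
            "n_fibers_extracted": res.n_fibers,
            "R_true": round(r_true, 4),
            "R_measured": round(res.R, 4),
            "abs_error": round(abs(res.R - r_true), 4),
        }
    )

df = pd.DataFrame(rows).sort_values("kappa")
df.to_csv(TABLES / "fiber_alignment.csv", index=False)
print(df.to_string(index=False))
mono = np.all(np.diff(df["R_measured"]) > 0)
print(f"\nmax |R_measured - R_true| = {df['abs_error'].max():.3f}; "
      f"monotone in kappa: {bool(mono)}")
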
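#!/usr/bin/env python
"""Seven-group irregular-breathing film experiment.

Same protocol as the sine experiment but driven by 60 s human-like
breathing traces scaled to 10/20/30 mm peak-to-peak displacement (the
first 44.4 s are irradiated). Writes results/experiment_breathing/.
"""
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import respcomp as rc
from respcomp.experiment import load_config, paper_profile_path, run_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "experiment_breathing"

cfg = load_config(paper_profile_path().with_name("breathing.yaml"))
result = run_experiment(cfg, OUT)
print(result.summary.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

fig, ax = plt.subplots(figsize=(6, 4))
prof = rc.profile(result.standstill)
ax.plot(prof[:, 0], prof[:, 1], "k-", label="standstill")
for name in ("resp30_uncomp", "resp30_comp"):
    prof = rc.profile(result.arms[name].grid)
    ax.plot(prof[:, 0], prof[:, 1], label=name)
ax.set_xlabel("position on film (mm)")
ax.set_ylabel("dose (cGy)")
ax.axvspan(25, 55, alpha=0.08, color="C0")
ax.legend()
fig.tight_layout()
fig.savefig(OUT / "profiles_30mm.png", dpi=120)
print(f"\nartifacts written to {OUT}")
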
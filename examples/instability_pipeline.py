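"""Shallow-WGS instability scoring, end to end on a synthetic cohort.

Simulates 14 healthy controls and 4 patients (tumor fractions 0 to 0.3)
carrying arm-level gains and losses, removes the shared GC bias by LOESS,
builds the reference panel, and scores each patient.  The I-score (sum of
|Z| over bins with |Z| > 2) rises with tumor fraction; the S-score (sum of
all squared Z) moves the same way but carries the sub-threshold noise too.
"""

import plasmacna as pc
from plasmacna.gcnorm import raw_to_percent

cfg = pc.SimulationConfig(seed=11, n_patients=4,
                          tumor_fractions=(0.0, 0.1, 0.2, 0.3))
controls, patients, gc, binset, truth = pc.simulate_bin_counts(cfg)

panel = pc.build_panel([raw_to_percent(c, gc, binset) for c in controls])
print(f"panel: {panel.n_controls} controls, "
      f"{int(panel.scorable.sum())}/{len(binset)} scorable bins")

for patient, tf in zip(patients, truth.tumor_fractions):
    prof = pc.profile_sample(raw_to_percent(patient, gc, binset), panel)
    n_gain = (prof.calls == "gain").sum()
    n_loss = (prof.calls == "loss").sum()
    print(f"{prof.sample_id}  tumor fraction {tf:.2f}  "
          f"I-score {prof.i_score:7.1f}  S-score {prof.s_score:8.1f}  "
          f"gains {n_gain:3d}  losses {n_loss:3d}")

# A sample sitting exactly on the panel means scores zero by construction.
from plasmacna.counting import STAGE_NORMALIZED, BinCounts

exact = BinCounts("panel_mean", panel.mean_pct.copy(), stage=STAGE_NORMALIZED)
print("exact-mean sample I-score:",
      pc.i_score(pc.zscores(exact, panel)))
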
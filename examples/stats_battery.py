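"""Run the 4×3 repeated-measures ANOVA battery on an ERD/ERS table.

Builds per-subject cell means for two electrodes with a strong
suboptimal-controlled (Type 3) low-alpha ERD injected at FC2 only, then
runs one ANOVA per (band, electrode) with Mauchly-gated Huynh–Feldt
correction and Fisher LSD post-hocs on significant main effects.
"""

import numpy as np
import pandas as pd

import preshot as ps

rng = np.random.default_rng(42)
rows = []
for band in ("theta", "low_alpha"):
    for channel in ("FC2", "CP6"):
        for s in range(10):
            for ptype in (1, 2, 3, 4):
                for interval in range(3):
                    val = rng.normal(scale=5.0)
                    if band == "low_alpha" and channel == "FC2" and ptype == 3:
                        val += 15.0      # injected performance effect
                    rows.append((f"S{s:02d}", ptype, band, channel,
                                 interval, val))
table = pd.DataFrame(rows, columns=["subject", "performance_type", "band",
                                    "channel", "interval", "erders_pct"])

battery = ps.run_stats_battery(table)
print("significant effects (p < .05), in the published table layout:")
print(battery["significant"].to_string(index=False))

print("\nFisher LSD pairwise comparisons for the detected effect:")
post = battery["posthoc"]
sel = post[(post["band"] == "low_alpha") & (post["channel"] == "FC2")
           & (post["level_j"] == 3)]
print(sel.to_string(index=False))
# A positive mean_diff against level 3 means that type shows less ERD
# than the suboptimal-controlled state; df is the ANOVA error df (27).
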
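"""The group-statistics battery on summary statistics and simulated data.

Summary-statistic entry points make printed group tables directly checkable;
the mixed repeated-measures ANOVA handles a between factor (group) crossed
with within factors (day, recording minute) and reports Mauchly's sphericity
test plus the conditionally applied Greenhouse-Geisser correction.
"""

import numpy as np
import pandas as pd

from vigikit import (chi_square_2x2, mann_whitney_u, mixed_rm_anova,
                     pooled_t_from_summary, welch_t_from_summary)

# depression severity, patients (n=27) vs controls (n=16), from group summaries
r = welch_t_from_summary(15.63, 3.835, 27, 1.25, 1.949, 16)
print(f"Welch t (severity, patients vs controls): t = {r.statistic:.3f}, "
      f"df = {r.df:.1f}, p = {r.p:.2g}")

r = pooled_t_from_summary(35.71, 10.457, 17, 48.20, 16.158, 10)
print(f"pooled t (age, responders vs non-responders): t = {r.statistic:.3f}, "
      f"p = {r.p:.3f}")

r = chi_square_2x2(10, 17, 7, 9)
print(f"chi-square (sex distribution): X2 = {r.statistic:.3f}, p = {r.p:.3f}")

# mixed rm-ANOVA on simulated per-minute values
rng = np.random.default_rng(0)
rows = []
for g, n, shift in [("patient", 10, 0.8), ("control", 8, 0.0)]:
    for s in range(n):
        base = rng.normal(0, 0.5)
        for minute in range(5):
            rows.append({"subject": f"{g}{s}", "group": g, "minute": minute,
                         "mvv": 4.5 + shift + base - 0.1 * minute
                         + rng.normal(0, 0.3)})
tbl = mixed_rm_anova(pd.DataFrame(rows), dv="mvv", subject="subject",
                     within=["minute"], between="group")
print(tbl[["effect", "F", "df1", "df2", "eps", "mauchly_p",
           "p_reported"]].round(4).to_string(index=False))

r = mann_whitney_u([11, 10, 11, 9, 10], [4, 6, 3, 7, 5])
print(f"Mann-Whitney U (stability scores): U = {r.statistic:.0f}, "
      f"p = {r.p:.4f} ({r.note})")
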
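"""Cohort statistics for a ten-patient bilateral monitoring table.

Feeds a reference table of per-side embolus counts (five intra-cardiac and
five CABG-only procedures) through the reporting module and prints the
summary a clinical study would quote: per-side medians with IQRs, the
paired left-vs-right t-test and the intra-cardiac vs CABG rank-sum test.
"""

from airemboli import CohortTable, PatientSummary, cohort_report

LEFT = [502, 349, 2785, 409, 2080, 480, 674, 196, 950, 284]
RIGHT = [596, 322, 3691, 383, 2144, 886, 843, 175, 601, 317]
PROCEDURES = ["MVR", "combined", "combined", "CABG", "combined",
              "MVR", "CABG", "CABG", "CABG", "CABG"]
VOLUMES = [0.021, 0.016, 0.005, 0.0003, 0.12, 0.003, 0.04, 0.0002, 0.022, 0.01]

table = CohortTable([
    PatientSummary(id=str(k + 1), n_emboli_left=l, n_emboli_right=r,
                   total_volume=v, procedure=p)
    for k, (l, r, v, p) in enumerate(zip(LEFT, RIGHT, VOLUMES, PROCEDURES))
])
r = cohort_report(table)

print(f"patients: {r['n_patients']}; per-operation totals "
      f"{r['min_total']}-{r['max_total']} emboli")
print(f"total air volume per patient: "
      f"{r['total_volume_range_ml'][0]}-{r['total_volume_range_ml'][1]} mL")
print(f"left  median {r['left']['median']} (IQR {r['left']['q1']:.0f}-{r['left']['q3']:.0f})")
print(f"right median {r['right']['median']} (IQR {r['right']['q1']:.0f}-{r['right']['q3']:.0f})")
t = r["left_vs_right"]
print(f"left vs right: paired t = {t['t']:.2f} (df {t['df']}), p = {t['p']:.2f}")
g = r["intra_cardiac_vs_cabg"]
print(f"intra-cardiac vs CABG: rank-sum z = {g['z']:.2f}, p = {g['p']:.2f} "
      f"(medians {g['intra_median']:.0f} vs {g['cabg_median']:.0f}; "
      f"means {g['intra_mean']:.0f} vs {g['cabg_mean']:.1f})")
print(
    "\nNeither test reaches significance at n = 10: bilateral counts are"
    "\nsymmetric, and the heavier intra-cardiac burden is driven by a few"
    "\npatients (hence median and mean are reported side by side)."
)
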
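"""Audit the packaged Japanese vaginal-birth cohort and print the funnel.

Fourteen dyads observed for 60 minutes after vaginal birth.  The script runs
each dyad through the pathway engine and prints the Robson-group × pathway
audit matrix: how many dyads started (prebirth), stayed on the best-practice
path at each step, and where the rest left it.
"""

from ssc_audit import build_japan_cohort, render, run_pathway, tabulate

records = build_japan_cohort()
results = [run_pathway(r) for r in records]
report = tabulate(results)

print(render(report, "markdown"))
totals = report.totals.as_dict()
print(f"{totals['prebirth_n']} dyads: all {totals['immediate_n']} reached "
      f"skin-to-skin within 5 minutes; {totals['continuous_n']} stayed in "
      f"continuous contact through the first hour; staff interfered with "
      f"{totals['staff_interfered_n']}; {totals['met_standard_n']} progressed "
      f"to self-attached suckling (met the full standard).")
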
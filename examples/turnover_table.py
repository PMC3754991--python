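"""Estimate subadult bone turnover from tissue-level physiology.

Builds the discrete per-year mineral and collagen turnover rates for
ages 0-20, smooths the collagen rates into the quartic polynomial used
by the forward model, and prints the cumulative-replacement milestones.
"""

from scipy.optimize import brentq

from weanabc import default_turnover_table, fit_qp, integrated_turnover

table = default_turnover_table()
qp = fit_qp(table)

print("age interval  mineral  collagen  collagen(QP)")
for i in (0, 1, 5, 10, 19):
    print(
        f"  {table.interval_start[i]:2d}-{table.interval_end[i]:<2d}      "
        f"{table.mineral[i]:6.3f}   {table.collagen[i]:6.3f}      "
        f"{qp.rate(float(table.interval_end[i])):6.3f}"
    )

first_year = integrated_turnover(qp, 0.0, 1.0)
age_966 = brentq(lambda a: integrated_turnover(qp, 0.0, a) - 0.966, 0.05, 3.0)
late = integrated_turnover(qp, 19.0, 20.0)
print(f"\ncollagen replaced over the first year    : {first_year:.3f}")
print(f"age when cumulative replacement hits 0.966: {age_966:.2f} yr "
      f"(~{age_966 * 52:.0f} wk)")
print(f"collagen replaced over year 19-20        : {late:.3f}")
print(
    "\nRates above 1/yr in infancy mean a rib is rebuilt faster than once a"
    "\nyear, so infant bone tracks diet almost immediately; by the late teens"
    "\nonly ~13% of collagen is replaced per year and bone averages over a"
    "\ndecade of diet."
)
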
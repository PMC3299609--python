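"""Reproduce the study's headline numbers from the packaged cohort margins.

The costing model is linear in unit prices, so confidence intervals, cost
shares, the annualized burden and the secondary-care estimate all follow
from the published component totals without patient-level data.
"""

from shouldercoi import (
    annualize,
    estimate_secondary_costs,
    load_paper_margins,
    run_method_switch,
    subgroup_report_from_margins,
    summarize_cohort,
)

fx = load_paper_margins()
rep = summarize_cohort(margins=fx.full)

total = rep.component("total")
hc = rep.component("healthcare_total")
print(f"n = {rep.n} patients over six months")
print(f"mean total cost      : EUR {total.mean:7.0f}  95% CI ({total.ci95[0]:.0f}, {total.ci95[1]:.0f})")
print(f"mean healthcare cost : EUR {hc.mean:7.0f}  95% CI ({hc.ci95[0]:.0f}, {hc.ci95[1]:.0f})")
print(f"annual total cost    : EUR {annualize(total.mean):7.0f} per patient (six-month mean x 2)")

print(f"\nsick leave is {100 * rep.shares_of_total['sick_leave']:.0f}% of total cost; "
      f"physiotherapy is {100 * rep.shares_of_healthcare['pt']:.0f}% of healthcare cost")

sub = subgroup_report_from_margins(fx.full, fx.high_cost, threshold=fx.threshold)
print(f"the {sub.n_subgroup} patients above EUR {sub.threshold:.0f} carry "
      f"{100 * sub.share_of_total_cost:.0f}% of total and "
      f"{100 * sub.share_of_healthcare_cost:.0f}% of healthcare costs")

fr = run_method_switch(fx.full)
print(f"\nfriction-cost method : EUR {fr.new_total_mean:.0f} per patient "
      f"({fr.pct_change_total:.1f}% vs human capital)")

sec = estimate_secondary_costs(29, 10, 4)
print(f"secondary care (29 referrals, 10 MRI, 4 surgeries): EUR {sec:.0f}, "
      f"about a third of the primary-care healthcare total")
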
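"""Bootstrap the incremental cost-effectiveness ratio and trace the CEAC.

Each of 1,000 replicates resamples the cohort with replacement and
records the mean cost, mean discounted QALY gain and their ratio; the
CEAC reports, at each willingness-to-pay threshold, the fraction of
replicates with positive net monetary benefit.
"""

import numpy as np

from rrdcua import (BootstrapSettings, EconParams, bootstrap_cua, ceac,
                    default_life_table, generate_cohort, GeneratorParams,
                    project_cohort, verdict, wtp_at_probability)
from rrdcua.qaly import projected_gains

cohort = generate_cohort(GeneratorParams(n=98, seed=1))
params = EconParams()  # WTP threshold = 3 x GDP per capita = 115,062 CNY/QALY

gains = projected_gains(project_cohort(cohort, default_life_table(), params))
res = bootstrap_cua(cohort.costs(), gains,
                    BootstrapSettings(replications=1000, seed=1))

print(f"mean cost      : {res.mean_cost:,.0f} CNY "
      f"(95% CI {res.cost_ci[0]:,.0f} - {res.cost_ci[1]:,.0f})")
print(f"mean QALY gain : {res.mean_qaly:.3f} "
      f"(95% CI {res.qaly_ci[0]:.3f} - {res.qaly_ci[1]:.3f})")
print(f"mean ICER      : {res.mean_icer:,.0f} CNY/QALY "
      f"(ratio of means {res.icer_of_means:,.0f})")
print(f"verdict at WTP {params.wtp_threshold_cny_per_qaly:,.0f} CNY/QALY : "
      f"{verdict(res.mean_icer, params)}")

curve = ceac(res, np.arange(0.0, 150_001.0, 1_000.0))
for p in (0.5, 0.7, 0.9):
    lam = wtp_at_probability(curve, p)
    print(f"WTP needed for {p:.0%} chance of cost-effectiveness : {lam:,.0f} CNY/QALY")
print("The CEAC thresholds show how cheap a QALY must be valued before "
      "the surgery stops looking like good value.")
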
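"""Project a one-year utility gain over remaining life expectancy.

The surgery arm keeps its one-year utility for life; the hypothetical
untreated comparator stays at the pre-operative level, so the
incremental QALYs are the gain times the (discounted) remaining years
— with the first year counting half the gain, since utility rises
steadily during it.
"""

from rrdcua import (EconParams, annuity_factor, default_life_table,
                    lifetime_qaly_gain, remaining_life_expectancy)

table = default_life_table()   # synthetic stand-in table, ages 70-95
params = EconParams()          # 3% annual discount, linear first-year ramp

age, sex, gain = 78, "male", 0.07
L = remaining_life_expectancy(age, sex, table)
G = lifetime_qaly_gain(gain, L, params)

print(f"remaining life expectancy at {age} ({sex}) : {L:.2f} years")
print(f"discount factor for those years          : "
      f"{annuity_factor(max(L - 1, 0), params.discount_rate):.3f} "
      f"(of {max(L - 1, 0):.2f} undiscounted)")
print(f"discounted QALYs gained from a {gain:.2f} utility gain : {G:.3f}")
print("Half the gain accrues during the ramp-up year; the rest is an "
      "annuity over the remaining expectancy discounted at 3%/year.")
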
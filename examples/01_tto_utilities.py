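"""Time-trade-off utilities: from interview answers to a utility gain.

A respondent who expects 10 more years of life and would give up 2 of
them for permanently perfect vision values their current visual state
at 1 - 2/10 = 0.8 on the dead(0)-perfect(1) scale.
"""

from rrdcua import TtoResponse, tto_utility, utility_gain

pre_op = TtoResponse(years_expected=10, years_traded=2)
post_op = TtoResponse(years_expected=10, years_traded=1)

u_pre = tto_utility(pre_op)
u_post = tto_utility(post_op)
gain = utility_gain(u_pre, u_post)

print(f"pre-operative utility : {u_pre:.2f}")
print(f"1-year utility        : {u_post:.2f}")
print(f"utility gain          : {gain:.2f}")
print("The gain is the extra quality weight each remaining life year "
      "carries after surgery; projected over life expectancy it becomes "
      "QALYs gained.")
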
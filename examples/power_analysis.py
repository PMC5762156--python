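"""Study power: two-sample t-test via the noncentral t distribution.

With an effect size of d = 1.75 (from pilot motor-outcome data), five
animals per group give ~81% power at one-tailed alpha = 0.05 -- the basis
for the minimum group size.
"""

from strokephys import PowerParams, ttest_power

for n in (3, 4, 5, 6, 8):
    p = ttest_power(PowerParams(effect_size=1.75, n_per_group=n, alpha=0.05))
    marker = "  <- minimum group size (power > 80%)" if n == 5 else ""
    print(f"n = {n}/group: power = {p:.3f}{marker}")

two = ttest_power(PowerParams(effect_size=1.75, n_per_group=5, tails="two"))
print(f"(two-tailed at n = 5 the power would only be {two:.3f})")
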
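"""Solve a composite-outcome trial design and print its analytic quantities.

A two-arm trial of 2000 participants targets a 50% control-arm composite rate
built from two components correlated at rho = 0.10, with treatment odds
ratios 0.65 (component 1) and 1.00 (component 2). The script recovers the
component-level probabilities implied by that design and the analytic power
of the continuity-corrected chi-square test on the composite.
"""

from composite_het import ScenarioSpec, build_arm_designs, cc_chisq_power

spec = ScenarioSpec(or1=0.65, or2=1.00, n_participants=2000,
                    control_composite_rate=0.50, icc=0.10)
control, treatment = build_arm_designs(spec)

print(f"control:   p1 = p2 = {control.p1:.5f}, joint p11 = {control.p11:.5f}, "
      f"composite rate = {control.composite_rate:.4f}")
print(f"treatment: p1 = {treatment.p1:.5f}, p2 = {treatment.p2:.5f}, "
      f"composite rate = {treatment.composite_rate:.4f}")

n_c, n_t = spec.arm_sizes
power = cc_chisq_power(control.composite_rate, treatment.composite_rate,
                       n_t, spec.alpha, n_control=n_c)
print(f"analytic composite-test power at n = {spec.n_participants}: {100 * power:.1f}%")
print()
print("Each control participant has a 30.8% chance of each component event;")
print("treatment lowers component 1 to 22.4% and leaves component 2 unchanged,")
print("so the composite rate falls from 50.0% to 44.4% - a main effect the")
print("trial detects with the power printed above.")
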
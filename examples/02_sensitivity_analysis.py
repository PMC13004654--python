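"""One-at-a-time +/-10% sensitivity of steady-state TH for both designs.

The headline: with the amplifier in the brain (design A) the TH level is
insulated from thyroid, clearance and most other perturbations - only the
brain-side constants Kd3, Kd5, n5 move it appreciably.  Put the amplifier
in the thyroid (design B) and TH becomes hostage to nearly every constant
except the thyroid's own (k1, k2, n1).
"""

from hptaxis import classify_sensitivities, finite_difference_sensitivity, get_preset

for name in ("design_A", "design_B"):
    table = finite_difference_sensitivity(get_preset(name), delta=0.1)
    th = table.symmetric_matrix()["TH"]
    classes = classify_sensitivities(table, threshold=0.3)
    print(f"{name}: symmetric sensitivity of steady-state TH")
    for param, coeff in th.items():
        marker = " *" if param in classes["TH"]["sensitive"] else ""
        print(f"  {param:>4}: {coeff:+.3f}{marker}")
    print(f"  sensitive (|S| >= 0.3): {', '.join(classes['TH']['sensitive'])}")
    print()

print("A coefficient of +0.14 means a 10% parameter increase raises TH by")
print("only 1.4%: the feedback loop absorbs the perturbation.")
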
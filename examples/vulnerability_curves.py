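"""Xylem vulnerability curves of the 15 eucalypt species.

Loads the packaged trait registry and, for each species, recomputes the
water potentials at 12% and 50% conductivity loss from the Weibull
(b, c) parameters, alongside the loss already suffered at -2 MPa.
More negative P50 = more embolism-resistant xylem.
"""

import profitmax as pm

registry = pm.load_species_registry()

print(f"{'species':<18} {'b':>5} {'c':>5} {'P12':>6} {'P50':>6}  PLC@-2MPa")
for name, traits in registry.items():
    curve = traits.curve
    print(
        f"{name:<18} {curve.b:>5.2f} {curve.c:>5.2f} "
        f"{pm.pxx(curve, 0.12):>6.2f} {pm.pxx(curve, 0.50):>6.2f} "
        f"{pm.plc(-2.0, curve):>8.1f}%"
    )

most = min(registry.values(), key=lambda t: pm.pxx(t.curve, 0.50))
print(
    f"\nMost embolism-resistant: {most.species_name} "
    f"(P50 = {pm.pxx(most.curve, 0.50):.2f} MPa)"
)
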
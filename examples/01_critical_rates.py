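"""Critical sterilization thresholds from growth and survival.

Given a program's Malthusian multiplier R_m (its annual multiplication
factor at low density) and annual survival p = 1 - 1/lifespan, the
overall fraction of the population that must be sterile for decline is
s = (R_m - 1)/(R_m - p), and the fraction that must be newly sterilized
each year is s_a = s(1 - p).
"""

from rickertnr import (
    as_percent,
    critical_rates,
    malthusian_multiplier,
    survival_from_lifespan,
)

programs = [
    # (label, R_m, lifespan years, lifespan basis)
    ("private community (R_m 2.45, median lifespan 6 y)", 2.45, 6, "median"),
    ("university campus (r_m 0.16, median lifespan 4 y)",
     malthusian_multiplier(0.16), 4, "median"),
    ("county program    (R_m 4.1, mean lifespan 5 y)", 4.1, 5, "mean"),
]

for label, R_m, lifespan, basis in programs:
    p = survival_from_lifespan(lifespan, basis).p
    rates = critical_rates(R_m, p)
    print(f"{label}")
    print(f"  survival p = {p:.2f}")
    print(f"  critical overall neutering rate s   = {as_percent(rates.s)}%")
    print(f"  critical annual  neutering rate s_a = {as_percent(rates.s_a)}%")

# A program sterilizing a larger annual fraction than s_a should, under
# the model, be pushing its population downward.
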
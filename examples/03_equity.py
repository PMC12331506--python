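"""Gini-based equity assessment of hospital-bed distribution.

The Lorenz curve orders spatial units by beds per person; the Gini
coefficient G summarises the gap to perfect equality (G = 0).  Labels:
G < 0.40 relatively reasonable, 0.40-0.50 relatively large gap,
>= 0.50 highly unequal.
"""

import medaccess as m

# a small worked table: (population, beds) per sub-district
units = [
    (102_608, 2_210),   # one sub-district concentrating a third of the beds
    (150_000, 800),
    (120_000, 600),
    (90_000, 400),
    (95_000, 350),
    (110_000, 250),
    (130_000, 0),       # no inpatient capacity at all
]
report = m.gini_report(units, ids=[f"SD{k+1}" for k in range(len(units))])
print(f"Gini coefficient: {report.G:.3f} -> {report.label}")
print(report.table.to_string(index=False))

# and on a synthetic city's admin units
_, _, _, _, admin = m.generate_city(m.CityConfig(seed=1))
rep2 = m.gini_report([(u.population, u.beds) for u in admin])
print(f"\nsynthetic city bed Gini over {len(admin)} admin units: "
      f"{rep2.G:.3f} -> {rep2.label}")
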
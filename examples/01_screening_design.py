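"""Build the 15-run definitive screening design for the saponification campaign.

Four factors — reaction temperature (70-90 degC), reaction time (5-15 min),
lanolin solution mass fraction (0.15-0.35) and alkali dosage (0.116-0.123
kg/kg) — are screened at three levels each. The design is fold-over pairs
of an order-6 conference matrix (two fake columns dropped) plus three
centre runs, scheduled in ascending temperature so the oil bath never has
to cool down.
"""

import greenflow as gf

table = gf.generate_dsd(seed=1)
print(table.physical.assign(
    exec_position=[int(list(table.run_order).index(i)) + 1 for i in range(table.n_runs)]
).to_string(index=False))
print(f"\n{table.n_runs} runs; coded levels per factor:",
      {f.name: sorted(set(table.coded[:, j])) for j, f in enumerate(table.factors)})
print("Each row is one experiment; exec_position is the ascending-temperature schedule slot.")
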
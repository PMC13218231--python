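"""Sensitivity presets and the KRT capacity flag table.

Shows the drug-price sensitivity (80 % price reduction) and the per-year
kidney-replacement-therapy occupancy against the 2,500-2,700 patient
capacity band under current (15 %) uptake.
"""

import ckdsim as ck
from ckdsim.reporting import STANDARD_PRESETS, krt_capacity_report, run_sensitivity

bundle = ck.load_parameters()
config = ck.ScenarioConfig(seed=1, microsim_scale=0.05)

results, report = run_sensitivity(STANDARD_PRESETS["price_20"], bundle, config)
nmb_row = report.loc["NMB (million EUR)"]
print("NMB (million EUR) with SGLT2i price reduced to 20 %:")
print(nmb_row.to_string())
print("Cheaper drug acquisition moves the uptake scenarios toward cost "
      "saving earlier in the horizon.\n")

base = ck.run_scenario(config, bundle)
capacity = krt_capacity_report(base)
print(capacity.to_string(index=False))
above = capacity[capacity["capacity_flag"] == "above"]
if len(above):
    print(f"\nUnder 15 % uptake the prevalent KRT pool first exceeds the "
          f"capacity band in year {int(above['year'].iloc[0])} "
          f"({int(above['calendar_year'].iloc[0])}).")
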
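"""Project first-in-human exposure of MTMSA-Trp against mithramycin.

Derives observed clearances from the printed preclinical dose/AUC pairs,
projects human clearance by the three interspecies methods, simulates both
compounds at a 13 ug/kg IV bolus in 13-year-old 50-kg male physiology, and
prints the exposure-comparison table (plasma/liver AUC over 24 h, liver
partition, and ratios versus MTM).
"""

import mithrapbpk as mp

for name in ("MTM", "MTMSA-Trp"):
    compound = mp.load_compound(name)
    print(f"\n{name}: human clearance projections (mL/h)")
    for method, cl in mp.predict_human_clearance(compound).items():
        print(f"  {method:15s} {cl:10.1f}")

table = mp.human_exposure_table()
print("\nHuman 13 ug/kg IV bolus, 24 h at 30-min intervals:")
print(table.round(3).to_string(index=False))
# plasma_ratio_vs_mtm > 1 for every method: the analog's lower clearance
# (driven by its extreme plasma protein binding) projects a substantially
# higher plasma exposure than MTM at the same dose.
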
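"""Middle-out calibration: fit SpecPStc to (synthetic) mouse plasma PK.

Generates a noisy synthetic mouse study whose noise-free AUC matches the
observed value, then refits the specific permeability-surface-area product
with clearance held at the NCA value — the self-consistency step that
anchors the cross-species workflow.
"""

import mithrapbpk as mp
from mithrapbpk.engine import Regimen

mtm = mp.load_compound("MTM")
mouse = mp.get_physiology("mouse")
regimen = Regimen.bolus(2.0, "mg/kg")

observed, cl_used = mp.make_study(
    mtm, "mouse", regimen, noise_cv=0.15, seed=42, target_auc=1906.0,
)
cl_nca = mp.observed_clearance(2.0, mp.auc_loglinear(observed), "mg/kg")
report = mp.fit_spec_pstc(observed, mtm, mouse, regimen,
                          cl_nca * mouse.body_weight)

print(f"generating SpecPStc : {mtm.spec_pstc:.3e} mL/s/mL")
print(f"fitted SpecPStc     : {report.spec_pstc:.3e} mL/s/mL")
print(f"objective (1/Y^2 SS): {report.objective:.3g}; at bound: {report.at_bound}")
# A single noisy replicate lands within about 2-fold of the generating
# value (the median over many replicates is much tighter); the log-scale
# search is what lets the same routine handle the analog, whose optimum is
# two orders of magnitude smaller.
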
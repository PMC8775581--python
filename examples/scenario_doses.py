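"""Per-cell absorbed dose for the five subcellular-localization scenarios.

Computes Monte Carlo S-values for nucleus and cytoplasm sources (medium
analytically, uniform-bath equilibrium), then evaluates the clonogenic
assay scenarios at 1 MBq and prints the dose table and the ratios to the
culture-medium-only (CMO) scenario.  The ratio of a targeted scenario to
CMO measures how much the internalizing construct amplifies the per-cell
dose over the non-internalizing one.
"""

import numpy as np

import celldose as cd
from celldose.dosimetry import scenario_preset
from celldose.transport import TransportConfig

rng = np.random.default_rng(1)
model = cd.CellModel()

print("computing S-values (10,000 histories per source)...")
svalues = cd.compute_scenario_s_values(model, TransportConfig(), 10_000, rng)
for (src, tgt), sv in sorted(svalues.items()):
    print(f"  S({tgt:7s} <- {src:9s}) = {sv.gy_per_decay:.3e} Gy/decay")

a0 = 1e6  # 1 MBq
reports = {name: cd.scenario_dose(scenario_preset(name, "clonogenic"),
                                  a0, svalues, model)
           for name in ("1", "2", "1_efflux", "2_efflux", "cmo")}

print("\nclonogenic assay, A0 = 1 MBq, volume-share convention:")
print(f"{'scenario':>10s} {'cell dose Gy':>14s} {'nucleus dose Gy':>16s}"
      f" {'ratio vs CMO':>13s}")
for name, rep in reports.items():
    ratio = (cd.dose_ratio(rep, reports["cmo"])
             if name != "cmo" else 1.0)
    print(f"{name:>10s} {rep.dose_Gy['cell']:14.3f} "
          f"{rep.dose_Gy['nucleus']:16.3f} {ratio:13.2f}")

print("\nThe nucleus scenario (1) exceeds the cytoplasm scenario (2); the"
      "\nefflux scenarios are dominated by 14 days of decay in the medium,"
      "\ngiving a ratio near the analytic 0.3 + 0.7 A~(14 d)/A~(4 h) = 31.5.")
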
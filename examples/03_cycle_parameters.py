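"""Per-cycle spatio-temporal and force parameters from a pair of feet.

Simulates one realistic symmetric trial, detects events on both feet and
segments gait cycles. Each cycle yields stance, swing, single- and
double-support durations (single + double = stance exactly) and the mean
summed plantar pressure during single support.
"""

import numpy as np

from insolegait import condition_preset, detect_events, extract_cycle_parameters, simulate_condition
from insolegait.io import cycles_to_frame

config = condition_preset("TDM6-SYM-MGAIT", seed=3, trial_duration_s=30.0)
sim = simulate_condition(config)[0]

seqs = {f: detect_events(sim.recording(f))[0] for f in ("left", "right")}
params, curves, diag = extract_cycle_parameters(
    sim.left, seqs["left"], seqs["right"]
)

df = cycles_to_frame(params)
print(df.head(5).to_string(index=False))
print("...")
print(f"\n{diag.kept} cycles kept, {diag.dropped_coverage} dropped for "
      f"contralateral coverage gaps")
means = df[["stance_ms", "swing_ms", "single_stance_ms", "double_stance_ms",
            "mean_force_single_stance"]].mean()
print("\nmeans:", ", ".join(f"{k}={v:.1f}" for k, v in means.items()))
residual = (df.single_stance_ms + df.double_stance_ms - df.stance_ms).abs().max()
print(f"max |single + double − stance| = {residual:.2e} ms (exact by construction)")
print("\nStance is ~63 % of the gait cycle and the single-support force sits "
      "on the 8–9 kg·cm⁻² summed-pressure scale, as for a healthy adult at "
      "1.2 m/s; each of the 101-point force curves spans one stance phase.")
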
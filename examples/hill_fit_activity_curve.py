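"""Hill analysis of a K⁺-dependent ATPase activity curve.

Simulates a 12-point activity assay with 2% noise in the inverse-activation
regime (activity falls as K⁺ occludes the enzyme, K₀.₅ ≈ 5 mM, n ≈ 1 —
the signature of a single non-cooperative K⁺ site), fits the Hill equation
and reports bootstrap confidence intervals.
"""

import numpy as np

from ionsite import kinetics, synth

ladder_mM = np.array([0, 0.5, 1, 2, 3, 5, 7.5, 10, 15, 20, 30, 50], float)
curve = synth.make_activity_curve(
    n=1.0, K_half=5.0, v0=0.1, v_max=1.0, mode="inhibition",
    concentrations=ladder_mM, noise_sd=0.02, seed=0,
)

fit = kinetics.hill_fit(curve, "inhibition", bootstrap=500, seed=0)
print(f"Hill coefficient n = {fit.n:.2f}"
      f"  (95% CI {fit.bootstrap_ci['n'][0]:.2f}-{fit.bootstrap_ci['n'][1]:.2f})")
print(f"K_0.5 = {fit.K_half:.2f} mM"
      f"  (95% CI {fit.bootstrap_ci['K_half'][0]:.2f}-{fit.bootstrap_ci['K_half'][1]:.2f})")
print(f"v_max = {fit.v_max:.3f}, basal v0 = {fit.v0:.3f}, SS = {fit.residual_ss:.2e}")
print()
print("n close to 1 indicates a single K+ site; K_0.5 ~5 mM matches the")
print("cytoplasmic-occlusion affinity of the gate-closed mutant enzyme.")
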
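"""How accurately does the analysis chain recover known fluxes?

Simulates 100 cores spanning realistic conditions, runs the full analysis
on the sensor-level output, and compares recovered fluxes with the
closed-form ground truth — noise-free and with 2 μM sensor noise.
"""

import numpy as np

from sedflux.validation import RecoverySettings, flux_recovery_ensemble

quiet = flux_recovery_ensemble(100, seed=0)
noisy = flux_recovery_ensemble(
    100, seed=0, settings=RecoverySettings(noise_sd=2.0, noise_sd_ph=0.02, replicates=3)
)

print("noise-free (100 cores):")
print(f"  max |rel err| O2  : {np.nanmax(np.abs(quiet.rel_err_o2)) * 100:.2e} %")
print(f"  max |rel err| ΣH2S: {np.nanmax(np.abs(quiet.rel_err_h2s)) * 100:.2e} %")

print("\n2 μM sensor noise, 3 replicate profiles averaged:")
print(f"  O2  : median {np.nanmedian(np.abs(noisy.rel_err_o2)) * 100:.2f} %, "
      f"max {np.nanmax(np.abs(noisy.rel_err_o2)) * 100:.2f} %")
print(f"  ΣH2S: median {np.nanmedian(np.abs(noisy.rel_err_h2s)) * 100:.2f} %, "
      f"max {np.nanmax(np.abs(noisy.rel_err_h2s)) * 100:.2f} %")

small = noisy[noisy.true_flux_h2s < 1.0]
print(f"\n  cores with true sulfide flux < 1 mmol m⁻² d⁻¹: "
      f"median |rel err| {np.nanmedian(np.abs(small.rel_err_h2s)) * 100:.1f} % — "
      "near-zero fluxes are noise-floor limited, matching the ±25% "
      "uncertainty such fluxes carry in field reports.")
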
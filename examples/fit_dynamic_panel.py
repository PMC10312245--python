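"""Estimate the dynamic cooperation model on a panel with known truth.

Simulates y_it = 0.5*y_{i,t-1} + 0.002*year + 0.002*ip*year
                 + 1e-4*n_patients + 0.01*charlson + fe_i + eps_it
for 300 practices over 14 waves, then re-estimates it by two-step
Blundell-Bond system GMM with Windmeijer-corrected standard errors.  The
report mirrors the usual dynamic-panel table: coefficients, Sargan
overidentification test, Arellano-Bond AR(1)/AR(2) tests (AR(1) should be
strongly negative, AR(2) ~ 0 under white-noise errors), joint Wald test
and pseudo-R^2.
"""

from coopnet.dynamic_panel_gmm import GMMSpec, fit_system_gmm, format_report
from coopnet.synthetic_claims import generate_panel_from_model

truth = [0.5, 0.002, 0.002, 1e-4, 0.01]
panel = generate_panel_from_model(truth, fe_sd=0.05, noise_sd=0.05,
                                  n_nodes=300, n_years=14, rng_seed=42)
result = fit_system_gmm(panel, GMMSpec(instrument_lag_min=4,
                                       instrument_lag_max=11))

print(format_report(result, "System GMM on simulated dynamics"))
print()
print("truth:", dict(zip(result.coefficients.index, truth)))
print("The lagged-outcome and ip-by-year coefficients should sit within "
      "about two standard errors of their true values.")
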
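"""Recover hemodynamic parameters from a simulated BOLD timeseries.

A boxcar stimulus drives the balloon model (vasoactive signal, blood
inflow, venous volume, deoxyhaemoglobin); the BOLD observation equation
maps volume and deoxyhaemoglobin to the measured signal.  Three parameters
are estimated: the venous transit time and the signal decay rate (both on a
log scale, so positivity is automatic) and the stimulus efficacy.
"""

import numpy as np

import varlaplace as vl

spec = vl.hemo_spec(seed=42, duration=120.0)
times, inputs, y, model = vl.make_hemo(spec)
result = vl.fit_vl(model, y)

sd = np.sqrt(np.diag(result.q_beta.cov))
tau = float(np.exp(result.q_beta.mean[0]))
kappa = float(np.exp(result.q_beta.mean[1]))
print(f"free energy: {result.free_energy:.2f} nats, iterations: {result.iterations}")
print(f"transit time tau_h: true 2.00 s   posterior {tau:.2f} s")
print(f"signal decay kappa: true 0.64 /s  posterior {kappa:.2f} /s")
print(
    f"stimulus efficacy:  true {spec.true_beta[2]:.2f}     "
    f"posterior {result.q_beta.mean[2]:.2f} +/- {sd[2]:.2f}"
)

# The transit time is typically the least well determined of the three (its
# 90% interval is the widest); all three posteriors should bracket the
# generating values.
print("posterior sds (log tau, log kappa, efficacy):", np.round(sd, 3))
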
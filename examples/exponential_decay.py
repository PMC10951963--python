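"""Estimate the rate of an exponential decay observed in noise.

The model is dynamic: xdot = -exp(beta) * x with the state observed
directly.  The ODE is turned into an observation function by
local-linearization integration and fitted like any static model.
"""

import numpy as np

import varlaplace as vl

spec = vl.decay_spec(seed=42)
times, y, model = vl.make_decay(spec)
result = vl.fit_vl(model, y)

rate_mean = float(np.exp(result.q_beta.mean[0]))
print(f"free energy: {result.free_energy:.2f} nats, iterations: {result.iterations}")
print(
    f"log rate: true {spec.true_beta[0]:+.3f}  "
    f"posterior {result.q_beta.mean[0]:+.3f} +/- "
    f"{np.sqrt(result.q_beta.cov[0, 0]):.3f}"
)
print(f"implied decay rate exp(beta): {rate_mean:.3f} /s (true {np.exp(-1):.3f} /s)")

# The posterior over the log rate should bracket the generating value -1;
# exponentiating gives the decay rate in 1/seconds.
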
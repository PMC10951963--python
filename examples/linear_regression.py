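"""Fit a Bayesian linear regression with unknown noise precision.

Simulates 100 observations from y = b1 + b2*x + noise with an evenly spaced
covariate on [-50, 50], then recovers the intercept, slope and the noise log
precision jointly by free-energy ascent.
"""

import numpy as np

import varlaplace as vl

spec = vl.glm_spec(seed=42)
X, y, model = vl.make_glm(spec)
result = vl.fit_vl(model, y)

sd_b = np.sqrt(np.diag(result.q_beta.cov))
sd_l = np.sqrt(np.diag(result.q_lambda.cov))
print(f"converged: {result.converged} after {result.iterations} iterations")
print(f"free energy (approx. log evidence): {result.free_energy:.2f} nats")
for name, truth, mean, sd in [
    ("intercept", spec.true_beta[0], result.q_beta.mean[0], sd_b[0]),
    ("slope", spec.true_beta[1], result.q_beta.mean[1], sd_b[1]),
    ("log precision", spec.true_lambda[0], result.q_lambda.mean[0], sd_l[0]),
]:
    print(f"{name:>14}: true {truth:+.3f}  posterior {mean:+.3f} +/- {sd:.3f}")

# Each line shows the generating value next to the posterior mean and sd; the
# generating values should sit within about two posterior sds of the mean.
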
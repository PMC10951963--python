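"""Fit a user-defined nonlinear observation model.

Any function from a parameter vector to a predicted data vector can serve
as the observation model: here a saturating exponential approach to an
asymptote, y_i = a * (1 - exp(-r * t_i)), with the rate fitted on a log
scale.  The free-energy breakdown shows the accuracy/complexity trade-off
the objective optimises.
"""

import numpy as np

import varlaplace as vl

rng = np.random.default_rng(42)
t = np.linspace(0.0, 8.0, 40)
true_a, true_logr = 2.0, np.log(0.7)
clean = true_a * (1.0 - np.exp(-np.exp(true_logr) * t))
y = clean + 0.1 * rng.standard_normal(t.size)


def g(beta):
    amplitude, log_rate = beta
    return amplitude * (1.0 - np.exp(-np.exp(log_rate) * t))


model = vl.GenerativeModel(
    g=g,
    prior_beta=vl.GaussianDensity([1.0, 0.0], np.diag([4.0, 1.0])),
    prior_lambda=vl.default_hyperprior(1),
    precision=vl.PrecisionComponents([np.eye(t.size)]),
    name="saturating-exponential",
)
result = vl.fit_vl(model, y)

print(f"free energy: {result.free_energy:.2f} nats")
print(f"accuracy:    {result.breakdown.accuracy:.2f} nats")
print(f"complexity:  {result.breakdown.complexity:.2f} nats")
sd = np.sqrt(np.diag(result.q_beta.cov))
print(f"amplitude: true {true_a:.2f}  posterior {result.q_beta.mean[0]:.2f} +/- {sd[0]:.2f}")
print(f"log rate:  true {true_logr:+.2f}  posterior {result.q_beta.mean[1]:+.2f} +/- {sd[1]:.2f}")
noise_sd = float(np.exp(-0.5 * result.q_lambda.mean[0]))
print(f"noise sd:  true 0.10  posterior {noise_sd:.3f}")

# Accuracy minus complexity equals the free energy: a model earns evidence
# by fitting the data without moving its parameters far from the prior.
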
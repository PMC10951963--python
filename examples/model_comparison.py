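"""Choose between noise models by Bayesian model comparison.

The data are a regression whose first 50 observations are noisier than the
last 50.  Three candidate models — one, two or three precision components —
are fitted to the same data; their free energies approximate the log
evidences, and the softmax of free energies gives posterior model
probabilities.  The two-component model should win: the third component adds
flexibility the data do not support, and the complexity penalty built into
the free energy discounts it.
"""

import numpy as np

import varlaplace as vl
from varlaplace.models import hetero_components

spec = vl.hetero_spec(seed=42)
X, y, base = vl.make_hetero(spec)

free_energies = []
for n_components in (1, 2, 3):
    model = vl.GenerativeModel(
        g=base.g,
        prior_beta=base.prior_beta,
        prior_lambda=vl.default_hyperprior(n_components),
        precision=hetero_components(spec.size, n_components),
        name=f"{n_components}-component",
    )
    res = vl.fit_vl(model, y)
    free_energies.append(res.free_energy)

table = vl.compare(["1 component", "2 components", "3 components"], free_energies)
print(table)
print()
winner = table.model_names[int(np.argmax(table.posterior_probs))]
print(f"winning noise model: {winner}")

# The table lists each model's free energy, its log Bayes factor against the
# worst model, and its posterior probability; the 2-component row should
# carry essentially all the probability mass.
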
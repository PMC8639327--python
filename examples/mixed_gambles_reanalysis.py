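"""Loss aversion vs. variance aversion on 50/50 mixed gambles.

Simulates 30 loss-averse agents deciding on a gain/loss grid, refits the
loss-aversion logistic model and the mean-variance model, and prints the
lambda recovery and the correlation between loss aversion and the fitted
variance weight.
"""

import numpy as np

from riskval.experiments import mixed_gambles_recovery

rec = mixed_gambles_recovery(n=30, seed=5)

print(f"True lambda range: {rec.true_lambda.min():.2f} .. {rec.true_lambda.max():.2f}")
fitted = np.array([f.lam for f in rec.fits])
print(f"Fitted lambda range: {np.nanmin(fitted):.2f} .. {np.nanmax(fitted):.2f}")
print(f"Spearman(true lambda, fitted lambda) = {rec.lambda_rho:.3f}")
print(
    f"Spearman(lambda, beta_sigma) = {rec.lambda_sigma_rho:.3f} "
    f"(p = {rec.lambda_sigma_p:.2g})"
)
print(
    "\nlambda > 1 means losses weigh more than equal gains. The strongly\n"
    "negative lambda/beta_sigma correlation shows that what prospect theory\n"
    "calls loss aversion looks like variance aversion under a mean-variance\n"
    "description of the same choices — the two models are hard to tell apart."
)
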
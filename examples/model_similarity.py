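"""How similar are the three models' predictions on a fitted population?

Simulates 12 heterogeneous agents (a third per generating model), fits
all three models to each, and prints predictive accuracies, pairwise and
three-way choice agreement, cardinal/ordinal subjective-value
correlations, and the RT vs. value-difference correlation.
"""

import numpy as np

from riskval.experiments import similarity_population

report, trials, agents = similarity_population(n_agents=12, n_starts=5, seed=3)

print("Predictive accuracy (per model, averaged over participants):")
for m, acc in report.accuracy.items():
    print(f"  {m:>3}: {acc:.1%}")

print("\nChoice agreement between models (same predicted side):")
for (a, b), frac in report.pairwise_agreement.items():
    print(f"  {a}/{b}: {frac:.1%}")
print(f"  all three: {report.three_way_agreement:.1%}")

print("\nSpearman correlation of subjective values across models (pooled):")
for (a, b) in report.cardinal_rho:
    print(
        f"  {a}/{b}: cardinal rho = {report.cardinal_rho[(a, b)]:.3f}, "
        f"ordinal rho = {report.ordinal_rho[(a, b)]:.3f}"
    )
print(
    f"  mean cardinal = {np.mean(list(report.cardinal_rho.values())):.3f}, "
    f"mean ordinal = {np.mean(list(report.ordinal_rho.values())):.3f}"
)

print("\nRT vs |value difference| Spearman rho (negative = harder is slower):")
for m, rho in report.rt_rho.items():
    print(f"  {m:>3}: {rho:.3f}")

print(
    "\nHigh agreement and value correlations show the models are nearly\n"
    "interchangeable behaviorally; ranks agree even more than raw values."
)
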
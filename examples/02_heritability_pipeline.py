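"""Mixed-model heritability on a simulated chamber experiment.

Generates the randomized incomplete block design (4 blocks of six complete
and two incomplete sub-blocks per chamber), simulates a trait under the
variance-component model, Tukey-filters outliers, fits the REML mixed model
and reports genotype BLUPs with Cullis broad-sense heritability.
"""

import numpy as np

from rootpheno.phenostats import descriptive_stats, fit_mixed_model, tukey_filter
from rootpheno.sim import VarianceComponents, generate_design, simulate_phenotypes

design = generate_design(376, n_chambers=8, seed=0)
vc = VarianceComponents(
    sigma2_g=60.0, sigma2_block=10.0, sigma2_subblock=10.0, sigma2_e=120.0,
    chamber_effects=tuple(np.linspace(-5, 5, 8)),
)
table, truth = simulate_phenotypes(design, vc, traits=("TRL",), mu=230.0, dropout=0.04, seed=1)
print(f"design: 376 slots/chamber x 8 replicates = {len(design)} slots; "
      f"{len(table)} observations after blank dropout")

filtered, flags = tukey_filter(table, "TRL")
print(f"Tukey box-plot filter flagged {flags.sum()} observations ({100 * flags.mean():.2f}%)")

fit = fit_mixed_model(filtered, "TRL")
print("\nREML variance components (cm^2):")
for term, value in fit.variance_components.items():
    print(f"  {term:<28}{value:8.2f}")
print(f"Cullis broad-sense heritability H = {fit.heritability:.3f}")

true_eff = fit.genotype_effects.index.map(truth["TRL"]["genotype_effects"])
r = np.corrcoef(fit.genotype_effects, true_eff)[0, 1]
print(f"correlation of BLUPs with true genotype effects: r = {r:.3f}")
print(descriptive_stats(filtered, ["TRL"]).round(2))
print(
    "\nH close to sigma2_g r / (sigma2_g r + sigma2_e) says most of the"
    "\ngenotype-mean differences are heritable signal, not chamber noise."
)
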
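"""Synthetic chick cohort: model ladder, DIC, and predictive checks.

Generates a 234-chick cohort (daily checks to age 30, radio contact failing
after ~7 days on average, two partially-missing sex covariates), fits the
constant / piecewise(age 4) / random-walk hazard ladder, and prints the DIC
table, the winning model's covariate posteriors, and Bayesian p-values for
two failure-age discrepancy statistics.
"""

import numpy as np

from eventfuse import PloverConfig, fit_case_models, generate_plover_dataset
from eventfuse.mcmc import posterior_summary
from eventfuse.plover import plover_ppc

config = PloverConfig()
dataset = generate_plover_dataset(config, np.random.default_rng(11))
print(
    f"{len(dataset.radio_records)} known-fate and "
    f"{len(dataset.mark_records)} unknown-fate chicks "
    f"({(~dataset.truth.censored).sum()} true deaths)"
)

dic_table, fits = fit_case_models(dataset, n_iter=3_000, seed=11)
print("\nDIC model comparison (best first):")
print(dic_table.round(1).to_string(index=False))

winner = dic_table.iloc[0]["model"]
model, samples = fits[winner]
print(f"\nposterior summary of the {winner} model:")
print(posterior_summary(samples).round(3).to_string())

for stat in ("mean-failure-age", "per-individual-age-difference"):
    p = plover_ppc(model, samples, statistic=stat, seed=11)
    print(f"Bayesian p-value [{stat}]: {p:.3f}")
print(
    "\nInterior p-values (0.05-0.95) indicate the fitted hazard reproduces "
    "the observed\nfailure ages; values near 0/1 flag misfit - including "
    "age-biased selection of the\nknown-death subset, which this generator "
    "deliberately induces via early radio failure."
)
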
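"""Fit the integrated model to one simulated mixed-fate dataset.

Simulates 40 radio-collared (known fate) and 40 marked (unknown fate)
individuals under the seasonal two-hazard design implied by an annual
survival of 0.25, fits the three-parameter integrated model by adaptive
Metropolis, and prints the posterior summary next to the generating truth.
"""

import numpy as np

from eventfuse import SimConfig, fit_scenario_dataset, simulate_dataset
from eventfuse.hazards import SeasonCalendar
from eventfuse.mcmc import geweke_z, posterior_summary

config = SimConfig(annual_survival=0.25, detection_p=0.20, seed=1)
rng = np.random.default_rng(1)
radio, marked, truth = simulate_dataset(config, rng)
n_deaths = int((~truth.censored).sum())
print(f"simulated {len(radio)} radio + {len(marked)} marked records, "
      f"{n_deaths} deaths in {config.study_length:.0f} days")

samples = fit_scenario_dataset(
    radio, marked, config.schedule(),
    season=SeasonCalendar(config.hunting_start_day, config.hunting_end_day),
    n_iter=10_000, seed=2,
)
summary = posterior_summary(samples)
lam1, lam2 = config.true_rates()
summary["truth"] = [np.log(lam1), np.log(lam2), config.detection_p]
print(summary.round(4).to_string())
print("Geweke z per parameter:", np.round(geweke_z(samples), 2))
print(
    "\nlog_lambda1/2 are log daily hazards (off/in season); their posterior "
    "means should sit\nwithin ~2 sd of the truth, and p is the per-survey "
    "detection probability of marked animals."
)
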
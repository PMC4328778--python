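# eventfuse

Integrated Bayesian event-time survival analysis for studies where only some
individuals' fates are known.

Wildlife survival studies rarely observe death times directly.  Radio-collared
animals are checked periodically, so their death times are known to an
interval; animals carrying only a mark (a band, a tag, or a failed radio) are
resighted imperfectly, and their deaths are never observed at all.  Classical
event-time (continuous-time survival) methods need the first kind of data;
mark–resight methods handle the second.  `eventfuse` fits one model to both
at once, which is what lets the unknown-fate animals inform the hazard.

## The model

Time is continuous (days).  Each individual `i` enters the risk set at `e_i`
(staggered entry / left truncation) and carries a hazard

    h_i(u) = h_0(u) · exp(x_i' β),

with `h_0` piecewise-constant (seasonal two-rate, age-structured, or smooth
via a random-walk age effect) and exponentiated coefficients interpretable as
hazard ratios.  Survival over an interval is
`S(t0, t1) = exp(−∫ h(u) du)`, computed exactly.

The joint likelihood is `L = L1 × L2`:

* **L1 (known fate):** each radio-collared animal contributes
  `S(e, r) · [1 − S(r, s)]` for a death bracketed in `[r, s]`, or `S(e, r)`
  if right-censored (`s = ∞`).
* **L2 (unknown fate):** each marked animal contributes survival to its last
  sighting `t*`, a Bernoulli-product detection term with per-survey
  probability `p` over the surveys between entry and `t*` (collapsed to
  `p^nn (1−p)^(n−nn)` for constant `p`), and a *tail* term summing every
  explanation of the empty end of its history — death in some inter-survey
  interval (which censors later detection opportunities) or survival with
  repeated non-detection:

      tail = Σ_k [S(t*, t_{k−1}) − S(t*, t_k)] (1−p)^{k−1} + S(t*, t_K) (1−p)^K
           = 1 − p · Σ_k S(t*, t_k) (1−p)^{k−1}.

Both components share the hazard parameters α.  Posteriors use weak priors
(uniform(0,1) on `p`; uniform or Student-t/Gaussian presets on log hazards
and coefficients; an intrinsic first-order random-walk prior with increment
SD τ ~ uniform(0,5) for smooth age effects; Bernoulli data augmentation with
Gaussian(0.5, 0.05) hyperpriors for missing binary covariates) and are
sampled by adaptive block random-walk Metropolis, with a hit-and-run variant
available.  Diagnostics: Geweke z, (Brooks–)Gelman–Rubin PSRF (univariate +
multivariate), DIC, batch-means summaries, and posterior predictive checks
on failure-age statistics.

## Worked example

`examples/01_integrated_fit.py` simulates 40 radio-collared + 40 marked
individuals under a seasonal design (annual survival 0.25, a 92-day season
with twice the baseline hazard, weekly surveys, detection 0.20) and fits the
three-parameter integrated model:

```
simulated 40 radio + 40 marked records, 69 deaths in 477 days
               mean      sd  mc_error    q2.5  median   q97.5   truth
log_lambda1 -5.9351  0.1976    0.0085 -6.3170 -5.9311 -5.5397 -5.7980
log_lambda2 -5.1342  0.1751    0.0073 -5.4812 -5.1245 -4.8055 -5.1049
p            0.2120  0.0119    0.0005  0.1904  0.2118  0.2365  0.2000
Geweke z per parameter: [0.4  1.21 0.54]
```

`log_lambda1/2` are the log daily hazards outside/inside the elevated
season; both posterior means sit within one standard deviation of the
generating truth, and the detection probability of the marked animals is
recovered from their sighting histories alone.  The other examples cover the
bias/RMSE simulation harness (`02`), the chick case-study ladder with DIC,
missing-covariate imputation and predictive checks (`03`), and the
encounter-history CSV format (`04`).  A thin CLI (`eventfuse simulate | fit |
diagnose | table1 | plover-demo | ppc`) wraps the same functions.

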
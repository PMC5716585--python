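# acuityfit

Psychophysics toolbox for two-alternative forced-choice (2AFC) grating
acuity experiments — the kind used to measure visual acuity behaviourally
in animals and humans: a subject repeatedly chooses between a rewarded and
an unrewarded grating card while the gratings' spatial frequency is raised,
and the acuity threshold is the frequency at which discrimination falls to
a criterion level.

The package covers the full workflow:

* **stimulus geometry** — convert between printed card layout, viewing
  distance, visual angle and cycles per degree (cpd); render Gabor-patch
  cards (sinusoid × Gaussian envelope) as PNGs;
* **session design** — pseudo-randomised trial schedules under the
  standard constraints (side never repeats more than twice, left/right
  balanced per frequency, warm-up trials, interleaved or blocked modes);
* **synthetic observer** — simulate Bernoulli choice data from a
  ground-truth Weibull observer, so the whole pipeline is testable
  without animal data;
* **psychometric fitting** — maximum-likelihood Weibull fits
  ψ(x) = γ + (1 − γ − λ)(1 − e^−(x/a)^b) with guess rate γ = 0.5 and
  lapse rate λ ∈ [0, 0.2], and analytic interpolation of the
  75%-correct acuity threshold;
* **exact binomial criteria** — one-tailed tail probabilities, learning
  rules (15/20 on consecutive occasions; a run of six correct), and the
  model-free "highest significantly biased frequency" acuity estimate.

The 75% criterion is not a convention picked from thin air: with 20 trials
per frequency, 15/20 is the smallest count significantly better than
guessing (exact one-tailed P(X ≥ 15 | 20, ½) ≈ 0.021 < 0.05), so the
threshold level and the significance criterion coincide.

See `docs/methods.md` for the model conventions (in particular the
reversed performance axis used to drive an increasing Weibull with
performance that falls in frequency) and numerical details.

## Worked example

```python
import acuityfit as af

# a 20 cm card: angle and frequency depend on where you stand
af.visual_angle(0.20, 1.5)            # 7.628...  degrees at 1.5 m
af.visual_angle(0.20, 4.0)            # 2.864...  degrees at 4 m

# simulate a bright-light dog whose true 75% threshold is 12 cpd,
# 20 choices at each of 2, 4, ..., 16 cpd
data = af.make_study_fixture("dog_bright", true_threshold=12.0, seed=3)
fit = af.fit_ml(data)
print(round(fit.threshold_cpd, 1), round(fit.upper_asymptote, 2), fit.converged)
# 10.7 0.87 True

crit = af.significance_threshold_acuity(data)
print(crit.frequency, crit.k, round(crit.p_value, 4))
# 10.0 17 0.0013
```

The fitted threshold (10.7 cpd) is the frequency where the fitted curve
crosses 75% correct — close to the simulated truth of 12 cpd given 20
trials per frequency. The upper asymptote 0.87 is 1 − λ̂, the subject's
performance ceiling. The binomial estimate (10 cpd) is the highest tested
frequency where 17/20 correct is significantly better than guessing; it is
grid-quantised and may sit above or below the interpolated threshold.

Each script in `examples/` exercises one capability end-to-end and prints
what the numbers mean:

```
python examples/stimulus_cards.py      # geometry + Gabor rendering
python examples/session_design.py     # schedule generation + validation
python examples/fit_one_subject.py    # simulate, fit, both threshold estimates
python examples/full_study.py         # a 28-subject simulated cohort
```

There is also a thin CLI over the same functions:

```
acuityfit simulate --profile dog_bright --threshold 12 --seed 42 -o fixture.csv
acuityfit fit --input fixture.csv --out summary.csv --plots-dir figs/
acuityfit stimulus --cpd 10 --distance 1.5 -o card.png
acuityfit run --out-dir study_out    # full simulate -> fit -> criteria bundle
```

Real data enter the same pipeline as a CSV with columns
`subject_id, species, condition, frequency_cpd, n_correct, n_total`
(`acuityfit convert` ingests XLSX workbooks of individual choice data into
this schema).

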
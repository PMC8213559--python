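"""Fit the hierarchical power-law model and inspect the posterior.

y_ij ~ N(b0_j * x^(b1_j), sigma_e^2) on the normalised scale, with
participant-level intercepts and exponents.  The population exponent b1 is
the quantity of scientific interest: < 1 compressive, 1 linear, > 1
expansive.
"""

import warnings

import magest

warnings.filterwarnings("ignore", category=magest.models.ConvergenceWarning)

pop = magest.study_population(2, "standard", seed=4)
stim = magest.study_stimuli(2)
ds = magest.simulate_ratings(magest.draw_participants(pop), stim, "standard", pop)
clean, _ = magest.preprocess(ds)

samples = magest.fit(
    magest.PowerModelSpec(), clean, chains=4, warmup=1000, total_draws=4000, seed=5
)
print(samples.summary().round(3).to_string())
b1 = samples.flat("b1")
print(f"\ngenerating exponent: {pop.mean_a}; posterior: "
      f"{b1.mean():.3f} +/- {b1.std(ddof=1):.3f}")
print("an exponent well below 1 means brightness grows compressively with "
      "luminance under the standard format")
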
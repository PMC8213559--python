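"""Posterior predictive check: do replicate datasets look like the data?

Ten replicate response vectors are simulated from the fitted model's
likelihood at the observed design points; a well-fitting model places the
observed mean comfortably inside the spread of replicate means.
"""

import warnings

import magest

warnings.filterwarnings("ignore", category=magest.models.ConvergenceWarning)

pop = magest.study_population(2, "standard", seed=9)
stim = magest.study_stimuli(2)
ds = magest.simulate_ratings(magest.draw_participants(pop), stim, "standard", pop)
clean, _ = magest.preprocess(ds)
samples = magest.fit(
    magest.PowerModelSpec(), clean, chains=4, warmup=800, total_draws=3000, seed=10
)

rep = magest.posterior_predictive(samples, n_rep=10, seed=11, condition_label="standard")
print(f"observed mean rating: {rep.y.mean():.2f}")
print("replicate means:     ",
      " ".join(f"{m:.2f}" for m in rep.replicate_means()))
print(f"observed-mean quantile among replicates: {rep.observed_mean_quantile():.2f}")
print("a quantile near the centre (not 0 or 1) indicates the model "
      "reproduces the overall rating level")
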
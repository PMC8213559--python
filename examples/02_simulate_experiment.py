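"""Simulate one magnitude-estimation experiment.

Synthetic observers carry individual power-law response functions; each rates
8 test stimuli 5 times against the reference (modulus 10) in a given
response format.
"""

import magest

pop = magest.study_population(2, "standard", seed=1)
print(f"population: exponent {pop.mean_a} +/- {pop.sd_a}, "
      f"noise sd {pop.noise_sd} (normalised scale), "
      f"{pop.n_participants} participants x {pop.n_reps} reps")

stim = magest.study_stimuli(2)
participants = magest.draw_participants(pop)
ds = magest.simulate_ratings(participants, stim, "standard", pop)

print(f"simulated {len(ds.trials)} trials "
      f"({len(ds.trials) // pop.n_participants} per participant)")
print(ds.trials[["participant_id", "stimulus_id", "response"]].head(8).to_string(index=False))

gm = {sid: magest.geometric_mean_rating(*(magest.floor_zeros(ds)[0], sid))
      for sid in (1, 9)}
print(f"\ngeometric-mean rating, darkest stimulus (1 cd/m^2):   {gm[1]:6.2f}")
print(f"geometric-mean rating, brightest stimulus (100 cd/m^2): {gm[9]:6.2f}")
print("a compressive observer (exponent < 1) rates the 10x-brighter stimulus "
      "well below 10x the modulus")
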
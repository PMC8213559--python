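"""Trial-level preprocessing: flooring, exclusion, standard-scale recoding.

The unidirectional format collects a binary direction judgment plus a rating
at or above the modulus; below-reference trials are mapped back to the
standard scale with r' = 100/r, and trials whose direction contradicts the
physical stimulus relation are dropped.
"""

import magest

print(f"reciprocal recode of 20: {magest.recode_reciprocal(20.0)}")
print(f"reciprocal recode of 4:  {magest.recode_reciprocal(4.0)}\n")

pop = magest.PopulationSpec(mean_a=0.5, sd_a=0.15, noise_sd=0.08,
                            n_participants=10, direction_error_rate=0.05, seed=2)
stim = magest.luminance_stimulus_table()
ds = magest.simulate_ratings(magest.draw_participants(pop), stim, "unidirectional", pop)

clean, report = magest.preprocess(ds)
print(f"trials in:  {report.n_trials_in}")
print(f"trials out: {report.n_trials_out}")
print(f"zeros floored to {report.floor_value}: {report.n_zero_recoded} "
      f"({100 * report.fraction_zero_recoded:.2f}%)")
print(f"erroneous directions excluded: {report.n_erroneous_excluded} "
      f"({100 * report.fraction_erroneous_excluded:.2f}%)")
print("\nafter recoding, below-reference ratings sit below the modulus again:")
below = clean.trials[clean.trials["stimulus_id"] < 5]["response"]
print(f"  below-reference rating range: {below.min():.2f} .. {below.max():.2f}")
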
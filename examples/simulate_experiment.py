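"""Generate one synthetic cricket experiment with the study's design.

Builds the default 2 sexes x 2 diets x 2 mating treatments cohort (575
animals with the study's exact per-group sample sizes), draws each
animal's adult lifespan from its group's Gompertz mortality model, and
records nightly calling effort for every male from age 4, every 5 days,
until death.
"""

from cricketsen import ExperimentConfig, generate_experiment, validate_config

config = validate_config(ExperimentConfig(seed=1))
cohort, calling = generate_experiment(config, seed=1)

print("diet C protein:carbohydrate ratio 1 :", round(config.derived_pc_ratio("C"), 2))
print("diet P protein:carbohydrate ratio 1 :", round(config.derived_pc_ratio("P"), 2))
print()
print("cohort size:", len(cohort))
print(cohort.groupby(["sex", "diet", "mating"]).size())
print()
print("calling observations:", len(calling), "nightly recordings")
print(calling.head())
# Each cohort row is one animal with its adult lifespan in days; each
# calling row is one night's total calling time (seconds) for one male.
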
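"""Per-group lifespan table: median with bootstrap 95% CI and "maximum
lifespan" (median of the longest-lived 10%).

Mirrors the group-summary table of the study: 8 sex x diet x mating
groups, percentile bootstrap with 5000 resamples.
"""

from cricketsen import ExperimentConfig, generate_experiment, summarize_groups
from cricketsen.io import cohort_to_records

cohort, _ = generate_experiment(ExperimentConfig(seed=4), seed=4)
records = cohort_to_records(cohort)

table = summarize_groups(records, reps=5000, seed=4)
print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
# median: group median lifespan in days; ci_low/ci_high: percentile
# bootstrap interval; max_median: median of the top decile, the study's
# definition of maximum lifespan.
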
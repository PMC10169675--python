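# Reference base-case configuration.
#
# death_hr "literature" replaces the anomalous printed survivor death-HR row
# with hazard ratios >= 1 from the stroke outcomes literature; set to
# "printed" to use the published row verbatim (a warning will be logged).
# life_table may be the "us_like_2019" synthetic preset or a path to a real
# two-column (age, qx) CSV.
variant: base_case
death_hr: literature
life_table: us_like_2019
seed: 7
n_iter: 30000
cost_cv: 0.25
util_cv: 0.10
output_dir: baocea_out
parameters: {}
# example override:
# parameters:
#   discount_rate: 0.0
#   cost_evt_addon: 20000
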
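"""Generate a synthetic Likert survey with planted careless respondents.

Builds the default study: a 65-item battery (36 scored attitude items in
three correlated factors, one instructed attention check, two criterion
scales), 1,112 respondents of whom ~11.3% respond carelessly with an
agree-skewed archetype mix.
"""

from carescreen import assemble_study, default_sdas_config

cfg = default_sdas_config(seed=2025)
study = assemble_study(cfg)

print(f"respondents: {study.matrix.n_respondents}")
print(f"battery columns: {len(study.matrix.data.columns)}")
print(f"planted careless: {study.n_careless_true}")
print("archetype composition:")
for name, count in study.truth_labels.value_counts().items():
    print(f"  {name:24s} {count}")

# The truth labels let every downstream stage be checked against the
# generating process -- e.g. which flagged respondents really were careless.
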
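"""Reliability of the unscreened vs screened samples, in parallel.

Cronbach's alpha (with Feldt 95% CIs) and McDonald's omega for the total
scale and each subscale.  Under agree-skewed careless contamination the
reliability change concentrates in the subscales that contain
reverse-worded items.
"""

from carescreen import (
    ResponseMatrix,
    assemble_study,
    default_sdas_config,
    flag_instructed,
    recode_reverse,
    scale_reliability,
)

study = assemble_study(default_sdas_config(seed=2025))
design = study.design
recoded = recode_reverse(study.matrix, design)
flags = flag_instructed(study.matrix, design)

samples = {
    "unscreened": recoded.data,
    "screened": recoded.data.loc[~flags],
}
reports = {
    name: scale_reliability(ResponseMatrix(items), design)
    for name, items in samples.items()
}

print(f"{'scale':14s} {'alpha uns':>10s} {'alpha scr':>10s} {'delta':>8s}")
for scale in reports["unscreened"]:
    a_u = reports["unscreened"][scale].alpha
    a_s = reports["screened"][scale].alpha
    print(f"{scale:14s} {a_u:10.3f} {a_s:10.3f} {a_s - a_u:+8.3f}")
total = reports["screened"]["total"]
print(f"\nscreened omega_t = {total.omega_t:.3f}, "
      f"omega_h = {total.omega_h:.3f} "
      f"(ratio {total.ratio_h_t:.2f}; above 0.50 supports a total score)")
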
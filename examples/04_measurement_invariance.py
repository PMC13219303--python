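"""Measurement invariance between attentive and careless respondents.

Fits the configural / metric / scalar ladder to two independent groups:
attentive responders and purely acquiescent careless responders.  The
expected signature of acquiescence is metric invariance (equal loadings:
both groups' responses relate to the factors the same way) together with
scalar failure (unequal intercepts: careless respondents endorse
everything in the agreement direction regardless of content).
"""

from carescreen import (
    ResponseMatrix,
    default_sdas_config,
    invariance_sequence,
    recode_reverse,
)
from carescreen.simulate import simulate_attentive, simulate_careless

cfg = default_sdas_config(seed=2025, include_criteria=False)
scored = list(cfg.design.scored_items)
attentive = simulate_attentive(cfg, 986)
careless = simulate_careless(cfg, "acquiescent", 126, start_index=986)
att = recode_reverse(ResponseMatrix(attentive), cfg.design).data[scored]
car = recode_reverse(ResponseMatrix(careless), cfg.design).data[scored]

report = invariance_sequence(att, car, cfg.design)
print(f"{'model':12s} {'chi2':>9s} {'df':>5s} {'CFI':>7s} {'RMSEA':>7s} "
      f"{'dCFI':>8s} {'supported':>10s}")
for lv in report.levels:
    dcfi = "" if lv.delta_cfi is None else f"{lv.delta_cfi:+.3f}"
    sup = "baseline" if lv.supported is None else (
        "yes" if lv.supported else "no")
    print(f"{lv.level:12s} {lv.chi2:9.1f} {lv.df:5d} {lv.cfi:7.3f} "
          f"{lv.rmsea:7.3f} {dcfi:>8s} {sup:>10s}")
# Scalar failure means group mean comparisons on the raw scores would be
# biased: the groups differ in item intercepts, not (only) in the trait.
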
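"""Combining several methods' suggestions with the agreement guidelines.

The decision rules: (a) all methods agree -> retain that count; (b) a pair
agrees -> retain it; (c) no agreement but suggestions within one attribute
-> explore that range; (d) strong disagreement -> explore each suggestion.
"""

from cdmdim import combine_rules

cases = [
    {"PA_rm": 4, "FF": 4, "MC_AIC": 4},
    {"PA_rm": 4, "FF": 5, "MC_AIC": 4},
    {"PA_rm": 3, "FF": 5, "MC_AIC": 4},
    {"PA_rm": 2, "FF": 8, "MC_AIC": 5},
]
for suggestions in cases:
    rec = combine_rules(suggestions)
    if rec.decided is not None:
        outcome = f"retain K = {rec.decided}"
    else:
        outcome = f"explore K in {rec.explore}"
    print(f"{suggestions} -> step ({rec.step}): {outcome}")
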
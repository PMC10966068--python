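"""Disambiguate left- vs right-hemisphere volume effects.

An asymmetry shift can come from either hemisphere; per-hemisphere
Cohen's d on the raw volumes (with stratified bootstrap CIs) shows
which side drives it.  The generator plants effects on the left volume,
so the left-right difference in d should carry the planted sign while
the right hemisphere stays near zero.
"""

import asymkit

atlas = asymkit.default_atlas()
table = asymkit.adjust_site(
    asymkit.generate_cohort(asymkit.default_spec(seed=1), atlas), atlas
)

hemi = asymkit.hemispheric_effect_table(
    table, atlas, "16p11.2del", B=1000, seed=5
).set_index(["region", "hemisphere"])

for region in ("Planum Temporale", "Temporal Fusiform Cortex posterior"):
    print(region)
    for h in ("L", "R"):
        row = hemi.loc[(region, h)]
        print(f"  {h}: d={row['d']:+.2f}  95% CI [{row['ci_low']:+.2f}, "
              f"{row['ci_high']:+.2f}]")
print("\nleft-dominant effects reflect the generator's left-volume planting;")
print("an interval excluding zero marks a robust hemispheric volume change")
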
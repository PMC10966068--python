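"""Generate the packaged demo cohort and verify a planted effect.

The default synthetic spec mirrors the reference study conditions: 290
controls plus 552 carriers across eight CNV groups, 130 paired
gray-matter volumes per subject, three scanning sites, and per-region
asymmetry shifts planted in control-SD units.
"""

import asymkit

atlas = asymkit.default_atlas()
spec = asymkit.default_spec(seed=1)
table = asymkit.generate_cohort(spec, atlas)

print(f"cohort: {len(table)} subjects x {table.shape[1]} columns")
print(table["group"].value_counts().to_string())

# the 16p11.2 deletion group carries a +1.0 control-SD shift of the
# planum temporale asymmetry index; site adjustment recovers it cleanly
adjusted = asymkit.adjust_site(table, atlas)
ai = asymkit.compute_ai(adjusted, atlas)
pt = atlas.index("Planum Temporale")
d = asymkit.cohens_d(
    ai.group_values("16p11.2del")[:, pt], ai.group_values("control")[:, pt]
)
print(f"\nrealized planum temporale AI Cohen's d (16p11.2del vs controls): {d:.2f}")
print("expected ~1.0: the planted shift expressed as a standardized mean difference")
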
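"""Generate a synthetic two-group study: cells, ring widths, climate.

The generator emulates a Scots pine admixture experiment: nine trees in a
pure stand and nine in a mixed (pine-oak) stand, 62 years of monthly
climate with planted spring/summer droughts, and ~300 tracheids per ring
with an earlywood->latewood gradient.  A post-drought earlywood density
elevation is planted in the pure group only.
"""

from qwa import synthetic
from qwa.io import _default_droughts

config = synthetic.SyntheticConfig(
    seed=7,
    drought_spec=_default_droughts(),
    effect_spec=synthetic.EffectSpec(after={"pure": 1.15, "mixed": 1.0}),
)
ds = synthetic.generate_dataset(config)

print(f"cells:     {len(ds.cells):,} rows "
      f"({config.trees_per_group} trees/group x {config.n_years} years x "
      f"{config.cells_per_ring} cells)")
print(f"rings:     {len(ds.rings):,} rows")
print(f"climate:   {len(ds.climate):,} year-months")
print(f"planted drought years: {ds.truth['drought_years']}")
print()
print("cell table head:")
print(ds.cells.head(3).to_string(index=False))
print()
print("Lumen areas are in um^2, wall thicknesses in um; rel_pos is the "
      "cell's relative radial position in its ring (0 = ring start).")
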
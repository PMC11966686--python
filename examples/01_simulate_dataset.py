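"""Generate a ready-to-run synthetic monitoring dataset.

Writes a community abundance series (site x year x species), a trait table
with its type schema, a pure-birth phylogeny, daily temperatures along a
latitudinal gradient, and the default causal-model spec — everything the
pipeline consumes.
"""

import pandas as pd

from divstab import generate_example_dataset

cfg = generate_example_dataset("example_data", preset="small", seed=42)

ab = pd.read_csv(cfg.abundance)
print(f"abundance records : {len(ab)}")
print(f"sites             : {ab.site_id.nunique()}")
print(f"species observed  : {ab.species_id.nunique()}")
print(f"years             : {ab.year.min()}-{ab.year.max()}")
print(f"config written to : example_data/config.yaml")
# Each record is one species' effort-standardised abundance at one site in
# one sampled year; the 'small' preset samples every year so downstream
# site selection retains all sites.
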
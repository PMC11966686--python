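"""Decompose community stability into asynchrony and population stability.

Community stability S_com = mu_com / sigma_com (inverse CV of the summed
abundances) factors exactly as log S_com = log phi + log S_pop, where
phi >= 1 measures how much species-level fluctuations cancel in the total.
"""

import pandas as pd

from divstab import decompose_stability

# Two species over three years: A is constant, B trends upward.
matrix = pd.DataFrame({"A": [2.0, 2.0, 2.0], "B": [1.0, 3.0, 5.0]})
d = decompose_stability(matrix, site_id="demo")

print(f"community mean     mu_com    = {d.mu_com:.3f}")
print(f"community SD       sigma_com = {d.sigma_com:.3f}")
print(f"community stability S_com    = {d.S_com:.3f}")
print(f"population stability S_pop   = {d.S_pop:.3f}")
print(f"asynchrony          phi      = {d.phi:.3f}")
print(f"identity check: log S_com - (log phi + log S_pop) = "
      f"{d.log_S_com - (d.log_phi + d.log_S_pop):.2e}")
# phi = 1 here because only one species fluctuates: the community total
# moves in lockstep with species B, so nothing cancels and all stability
# comes from the (weighted) population stability term.
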
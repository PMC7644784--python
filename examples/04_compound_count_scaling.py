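"""How aggregate specific respiration scales with pool size.

Specific rates are per C-mol of biomass, so they should not depend on how
many compounds a model happens to include. Without regulation each extra
compound adds an independent pathway and the aggregate grows linearly;
cybernetic allocation normalizes activity and keeps it nearly flat.
"""

import numpy as np

from sxm import ZoneSpec, formulas_from_table, generate_formulas, profile_batch, scaling_experiment

pool = profile_batch(
    formulas_from_table(generate_formulas(ZoneSpec(n_compounds=500, seed=99)))
)
sizes = list(range(10, 101, 10))

plain = scaling_experiment(pool, sizes, mode="sxm", seed=5)
regulated = scaling_experiment(pool, sizes, mode="sxm_exm", seed=5)

print("  n   |r_O2| unregulated   |r_O2| regulated")
for (_, r1), (_, r2) in zip(plain.iterrows(), regulated.iterrows()):
    print(f"{int(r1.n_compounds):4d}   {r1.specific_r_o2:10.3f}        {r2.specific_r_o2:10.4f}")

x = plain["n_compounds"].to_numpy(float)
r = plain["specific_r_o2"].to_numpy()
slope = (x @ r) / (x @ x)
r2_fit = 1 - np.sum((r - slope * x) ** 2) / np.sum((r - r.mean()) ** 2)
spread = regulated["specific_r_o2"].max() / regulated["specific_r_o2"].min()
print(f"\nunregulated: linear through origin, slope {slope:.4f}/compound, R^2 = {r2_fit:.4f}")
print(f"regulated  : max/min across sizes = {spread:.3f} (nearly constant)")
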
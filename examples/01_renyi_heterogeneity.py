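"""Renyi heterogeneity basics: effective numbers of a discrete distribution.

Run:  python examples/01_renyi_heterogeneity.py
"""

import numpy as np

from endevs import gaussian_heterogeneity, renyi_heterogeneity

p = np.array([0.5, 0.25, 0.25])
print("distribution p =", p)
for q in (0, 0.5, 1, 2, np.inf):
    print(f"  Pi_{q}(p) = {renyi_heterogeneity(p, q):.4f}")

# A uniform distribution over n categories always counts exactly n,
# whatever the order q — the defining property of a numbers equivalent.
print("uniform over 5, q=2:", renyi_heterogeneity(np.full(5, 0.2), 2))

# Replication principle: three disjoint copies -> exactly 3x the heterogeneity.
p3 = np.tile(p / 3, 3)
print("replicated x3, q=1:", renyi_heterogeneity(p3, 1), "=", 3 * renyi_heterogeneity(p, 1))

# Continuous analogue for a Gaussian: an effective length, linear in sigma.
for sigma in (1.0, 2.0):
    print(f"Gaussian sigma={sigma}, q=1 -> effective length {gaussian_heterogeneity(sigma, 1):.4f}")

# The values above are effective counts: p behaves like ~2.8 equally likely
# categories at q=1, and a unit Gaussian occupies ~4.13 units of effective length.
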
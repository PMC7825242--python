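"""Which predictors drive CH4 emission?  Random-forest contributions.

Site-level model: climate (MAT, MAP), soil chemistry (TOC, TN, TP, pH),
network complexity (PC1 of the topology attributes) and Shannon diversity
against CH4 production potential.  The synthetic response is built with
the network term dominant, and the model recovers that ordering.
"""

import numpy as np
import pandas as pd

from methanocoexist import (generate_ch4, generate_metadata,
                            importance_to_contribution, rf_importance)
from methanocoexist.synthetic import SyntheticTruth

rng = np.random.default_rng(1)
meta = generate_metadata(30, 2, seed=1)
sites = sorted(meta["site_id"].unique())
x_net = dict(zip(sites, rng.normal(0, 1, 30)))     # network-complexity index
x_div = dict(zip(sites, rng.normal(2.0, 0.3, 30)))  # site-mean Shannon

truth = SyntheticTruth(seed=1)   # default CH4 coefficients: network dominant
meta = generate_ch4(meta, x_net, x_div, truth, seed=101)

site_meta = meta.groupby("site_id").first()
X = pd.DataFrame({
    "MAT": site_meta["mat"], "MAP": site_meta["map"],
    "TOC": site_meta["TOC"], "TN": site_meta["TN"],
    "TP": site_meta["TP"], "pH": site_meta["pH"],
    "network_index": pd.Series(x_net), "shannon": pd.Series(x_div),
})
y = site_meta["ch4_potential"]

res = rf_importance(X, y, n_trees=150, seed=1, n_perm_sig=19)
contrib = importance_to_contribution(res)

print(f"model variance explained (out-of-bag): {res.var_explained_pct:.1f}%\n")
print(f"{'predictor':15s}{'contribution':>13s}{'perm. p':>9s}")
for name in sorted(contrib, key=contrib.get, reverse=True):
    print(f"{name:15s}{contrib[name]:>12.1f}%{res.p_values[name]:>9.3f}")
print("\nThe network index carries the largest share of the importance,")
print("matching the planted response where interactions outweigh diversity")
print("and climate in driving methane production.")
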
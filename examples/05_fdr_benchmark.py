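"""Realized-FDR benchmark of the selection procedure on known ground truth.

Feature matrices with 900 null and 100 shifted columns are selected with
Mann-Whitney U + Benjamini-Yekutieli at q = 0.05; the false discovery
proportion among selected features is averaged over replicates.
"""

import reachkin as rk

res = rk.false_discovery_proportion_experiment(
    n_null=900, n_alt=100, shift=1.0, n_per_group=50,
    n_replicates=50, q=0.05, seed=1)

print(f"replicates:            {res['n_replicates']}")
print(f"mean FDP:              {res['mean_fdp']:.4f}  (target level q = {res['q']})")
print(f"mean true-positive rate: {res['mean_tpr']:.3f}")
# BY controls FDR under arbitrary dependence, so with independent columns
# it is conservative: the realized FDP sits well below the nominal 0.05
# while still detecting most of the shifted features.
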
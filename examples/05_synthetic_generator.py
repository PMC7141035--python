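"""The synthetic niche-conservatism generator and its recorded truth.

Generates a reserve network, prints the generative equations, and verifies
the four latitudinal signatures the construction is designed to produce.
"""

import json

import phyloldg as pl

config = pl.SimConfig(seed=11)
dataset = pl.simulate_dataset(config)

print(f"{config.n_reserves} reserves, {len(dataset.pool)} species "
      f"({dict(config.pool_sizes)})")
print("occupancy rule:", dataset.truth["occupancy_rule"])
print("generative equations:")
for name, eq in dataset.truth["equations"].items():
    print(f"  {name:<10} = {eq}")

print("\nlatitudinal pattern checks (alpha = 0.05):")
for check in pl.expected_patterns(dataset):
    print(f"  {check.name:<32} stat = {check.statistic:+.4f} "
          f"p = {check.p_value:.2g}  passed = {check.passed}")

null = pl.simulate_dataset(pl.SimConfig(seed=11, occupancy_filter="random"))
n_pass = sum(c.passed for c in pl.expected_patterns(null))
print(f"\nclimate-independent null: {n_pass}/4 patterns significant "
      "(the construction, not the analysis, creates the gradients)")
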
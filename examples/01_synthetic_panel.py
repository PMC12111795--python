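"""Generate and preprocess a synthetic wheat-storage panel.

Builds the standard full-factorial storage trial (4 moisture levels x
4 temperatures x 7 monthly samplings x 5 replicates = 560 records),
simulates degradation of the three quality indicators, injects 1.2%
random missingness, then repairs and screens the panel.
"""

from graincast import (
    generate_design,
    impute_missing,
    inject_missing,
    remove_outliers,
    simulate_quality,
    standardize,
)

panel = generate_design()
print(f"design records: {len(panel)}  (4 x 4 x 7 x 5)")

panel = simulate_quality(panel, seed=0)
panel = inject_missing(panel, rate=0.012, seed=1)
print(f"missing cells after injection: {panel.n_missing_cells} "
      f"of {len(panel) * 3}")

panel = impute_missing(panel)
panel, removed = remove_outliers(panel, z_threshold=3.0)
print(f"missing cells after repair: {panel.n_missing_cells}; "
      f"outlier records removed: {len(removed)}")

std = standardize(panel)
germ = std.scaler["germination_pct"]
print("germination standardization: "
      f"mean {germ['mean']:.2f}%, sd {germ['sd']:.2f}%")
print(panel.df.head(3).to_string(index=False))
# Each row is one replicate measurement under one storage condition;
# germination falls while fatty acid rises over time, faster when warm/damp.
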
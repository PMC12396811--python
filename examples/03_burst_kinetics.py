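"""Infer burst size and frequency along the trajectory and label their trends.

A gene is simulated with burst size ramped 12 -> 6 before the branch, 6 -> 14
on branch1 and 6 -> 3 on branch2 (burst frequency fixed at 0.5 per mRNA
lifetime).  Each overlapping pseudotime window gets a Beta-Poisson maximum-
likelihood fit; the per-segment burst-size series is labelled by its Spearman
correlation with window order.
"""

from branchdyn import (BurstFitOptions, assign_windows, burst_trajectory,
                       simulate_branching_dataset)
from branchdyn.bursts import burst_table
from branchdyn.scenarios import burst_trend_config

matrix, annotation = simulate_branching_dataset(burst_trend_config(seed=0))
windows = assign_windows(annotation, windows_per_segment=12, overlap_fraction=0.5,
                         branches=["pre", "branch1", "branch2"])
estimates, trends = burst_trajectory(matrix, annotation, windows, "Gene",
                                     BurstFitOptions(seed=0, quad_order=60))

table = burst_table(estimates, "Gene")
print(table[["branch", "window_index", "t_mid", "BS", "BF"]]
      .round(3).to_string(index=False))
print("\nburst-size trend per segment (label, Spearman rho):")
for branch, (label, rho) in trends.items():
    print(f"  {branch:8s} {label:12s} rho={rho:+.2f}")

# BS is the mean mRNA output per transcription burst (k_syn/k_off) and BF the
# burst rate per mRNA lifetime (k_on); the labels should recover the
# programmed decreasing / increasing / decreasing pattern.
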
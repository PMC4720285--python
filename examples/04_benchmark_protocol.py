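"""Repeated-run benchmark: mean(sd) cells over independent splits.

For each run the observed links are independently re-split into 90%
training / 10% probe; every predictor is refit on the training graph and
both metrics recorded.  Cells are printed as mean(sd), with the standard
deviation in units of 1e-4 — e.g. 0.8307(288) means 0.8307 +/- 0.0288.
"""

import nflink as nfl

net = nfl.planted_partition(100, 4, p_in=0.25, p_out=0.01, seed=5)
report = nfl.run_benchmark(
    net,
    methods=["NF", "CN", "AA", "RA", "PA"],  # NF cutoff: CV-selected once
    fractions=[0.9],
    runs=20,
    seed=17,
)
print(f"{'method':>7s}  {'AUC':>12s}  {'precision':>12s}")
for method in ("NF", "CN", "AA", "RA", "PA"):
    a_mean, a_sd = report.cell(method, 0.9, "auc")
    p_mean, p_sd = report.cell(method, 0.9, "precision")
    print(f"{method:>7s}  {nfl.format_mean_sd(a_mean, a_sd):>12s}  "
          f"{nfl.format_mean_sd(p_mean, p_sd):>12s}")
# Each column's sd reflects split-to-split variability, not method noise:
# all methods see the same splits, so differences in means are paired.
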
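"""Replicate statistics with Grubbs outlier screening.

Builds a replicate table (8 flow cells × 4 days) of a structural parameter
with one planted gross outlier and one missing value, runs the per-day
Grubbs screen, and prints the summary that would annotate a heat map.
"""

import numpy as np
import pandas as pd

from octbiofilm import ReplicateTable, replicate_summary

rng = np.random.default_rng(2)
values = pd.DataFrame(
    rng.normal(loc=[[20, 45, 70, 90]], scale=4.0, size=(8, 4)),
    index=range(1, 9),
    columns=range(1, 5),
)
values.iloc[4, 1] = 95.0       # planted outlier: flow cell 5, day 2
values.iloc[2, 0] = np.nan     # imaging artifact: missing value

table = ReplicateTable(values.round(1), parameter="substratum coverage", units="%")
summary = replicate_summary(table, alpha=0.05)
print(summary.round(2))
print("\noutlier mask (o = removed before the mean/median/SD):")
print(table.outliers.replace({True: "o", False: "."}))
print(
    "\nEach day's mean/median/SD uses only the surviving replicates; n_used\n"
    "says how many, and 'reliable' is False when fewer than 3 were available."
)
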
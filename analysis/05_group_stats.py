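#!/usr/bin/env python
"""Group comparisons on the synthetic soma dataset.

Applies the comparison battery used for such data — Mann–Whitney U for
relay vs interneuron areas, Kolmogorov–Smirnov for distribution shape,
Kruskal–Wallis with Dunn's post hoc across three synthetic laminae, and
one-way ANOVA with Tukey's HSD — and writes results/group_stats.json.

Run analysis/04_soma_mixture.py first (it writes the input CSV).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from coloc3d import multi_group_test, two_sample_test
from coloc3d.io import read_soma_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    soma_csv = ROOT / "scratch" / "soma_synthetic.csv"
    if not soma_csv.exists():
        raise SystemExit("run analysis/04_soma_mixture.py first")
    data = read_soma_csv(soma_csv)
    data = data[data["area_um2"] >= 40.0]
    relay = data.loc[data.gaba_status == "-", "area_um2"].to_numpy()
    inter = data.loc[data.gaba_status == "+", "area_um2"].to_numpy()

    out = {}
    for method in ("mannwhitney", "ks", "welch"):
        res = two_sample_test(relay, inter, method=method)
        out[f"relay_vs_interneuron_{method}"] = res.to_dict()
        print(f"{res.name}: statistic {res.statistic:.1f}, p = {res.p_value:.3g}")

    # synthetic laminae: split relay cells into three pseudo-strata with a
    # small size shift to exercise the multi-group paths
    rng = np.random.default_rng(0)
    strata = rng.integers(0, 3, size=relay.size)
    groups = {f"L{i+1}": relay[strata == i] + 8.0 * i for i in range(3)}
    for method, posthoc in (("kruskal", "dunn"), ("anova", "tukey")):
        res = multi_group_test(groups, method=method, posthoc=posthoc)
        out[f"laminae_{method}"] = res.to_dict()
        print(f"{res.name}: statistic {res.statistic:.2f}, p = {res.p_value:.3g}")
        for pair in res.posthoc:
            print(f"  {pair['comparison']}: adj p = {pair['p_adjusted']:.3g}")

    (ROOT / "results" / "group_stats.json").write_text(
        json.dumps(out, indent=2, default=float)
    )
    print("wrote results/group_stats.json")


if __name__ == "__main__":
    main()
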
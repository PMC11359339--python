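"""Descriptive ANOVAs: region and cultivar effects on flowering timing.

Summarises first flowering per orchard-year-cultivar stratum and runs
region x cultivar two-way ANOVAs on the stratum means and on the
within-stratum ranges. With the default generator the cultivars differ by
~17 days in mean flowering while the lower-chill region (Kerikeri) shows
more spread.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, default_config  # noqa: E402

from phenocast.describe import anova_two_way, stratum_table  # noqa: E402
from phenocast.synthetic import simulate_dataset  # noqa: E402


def main() -> None:
    config = default_config()
    dataset = simulate_dataset(config.synthetic)
    strata = stratum_table(dataset.flowering)

    RESULTS.mkdir(exist_ok=True)
    strata.round(2).to_csv(RESULTS / "flowering_strata.csv", index=False)
    for response, name in (("mean_doy", "anova_mean_doy"),
                           ("range_days", "anova_range_days")):
        result = anova_two_way(strata, response)
        result.table.round(4).to_csv(RESULTS / f"{name}.csv", index=False)
        print(f"\nANOVA on {response} ({len(strata)} strata):")
        for _, row in result.table.iterrows():
            print(f"  {row['term']}: F({row['df_num']},{row['df_den']}) = "
                  f"{row['F']:.1f}, p = {row['p']:.3g}")
        if response == "mean_doy":
            gm = result.group_means.set_index(["factor", "level"])
            for cv in ("Zesy002", "Hayward"):
                m = gm.loc[("cultivar", cv)]
                print(f"  {cv}: {m['mean']:.1f} +/- {m['se']:.1f} d")


if __name__ == "__main__":
    main()
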
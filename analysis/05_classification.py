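"""Presence/absence classification baseline (logistic GLM vs random forest).

Labels one instance per vine per 3-day date between 1 Sep and 31 Dec and
predicts flowering from DD/CU on 1 September plus region and cultivar.
Because the predictors are constant within a vine-year, the classifiers
cannot localise the flowering date - the expected (and observed) poor
performance that motivates the regression approach.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, default_config  # noqa: E402

from phenocast.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    config = default_config()
    report = run_pipeline(config)
    RESULTS.mkdir(exist_ok=True)
    report.classification_table.round(1).to_csv(
        RESULTS / "classification_confusion.csv", index=False)
    report.classification_metrics.round(1).to_csv(
        RESULTS / "classification_metrics.csv", index=False)

    overall = report.classification_metrics.query("region == 'all'")
    print(report.classification_table.round(1).to_string(index=False))
    print()
    for _, row in overall.iterrows():
        print(f"{row['model']}: accuracy {row['accuracy_pct']:.1f}%, "
              f"sensitivity {row['sensitivity_pct']:.1f}%, "
              f"specificity {row['specificity_pct']:.1f}%")


if __name__ == "__main__":
    main()
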
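"""Stage 2: candidate flowering regressions, refinement, intervals, CV.

Runs the full pipeline (weather -> budbreak -> covariates), compares the
nine candidate models with full interactions on the 2016-2019 training
years, refines the AIC-best candidate by stepwise AIC, and reports 99%
prediction-interval widths and coverage on the 2020-2021 test years plus
5-fold cross-validation of the refined model.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, default_config  # noqa: E402

from phenocast.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    config = default_config()
    report = run_pipeline(config)

    RESULTS.mkdir(exist_ok=True)
    report.candidate_table.round(2).to_csv(RESULTS / "candidate_models.csv", index=False)
    report.prediction_table.round(2).to_csv(RESULTS / "predictions_best_model.csv",
                                            index=False)
    cv = {k: v for k, v in report.cv_results.items() if not k.endswith("_folds")}
    with open(RESULTS / "cv_results.json", "w") as fh:
        json.dump(cv, fh, indent=2)

    print(report.candidate_table.round(2).to_string(index=False))
    best = report.candidate_table.set_index("model").loc[f"{report.best_label}_1"]
    print(f"\nselected model: {report.best_label} (stepwise-refined)")
    print(f"  99% interval width {best['interval_min']:.1f}-{best['interval_max']:.1f} d, "
          f"coverage {best['coverage_pct']:.1f}%, R2 {best['r2']:.2f}")
    print(f"5-fold CV RMSE {cv['rmse_mean']:.2f} d "
          f"(range {cv['rmse_min']:.2f}-{cv['rmse_max']:.2f}), "
          f"R2 {cv['r2_mean']:.2f} (range {cv['r2_min']:.2f}-{cv['r2_max']:.2f})")


if __name__ == "__main__":
    main()
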
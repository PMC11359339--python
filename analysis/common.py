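"""Shared configuration for the analysis scripts.

All drivers use the same synthetic study: two regions x three orchards x
six seasons (2016-2021) x eight vines, trained on 2016-2019 and tested on
2020-2021. Small summary tables go to results/; bulky per-hour or per-survey
tables go to scratch/.
"""

from pathlib import Path

from phenocast.config import PipelineConfig, SyntheticConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 11


def default_config(seed: int = SEED) -> PipelineConfig:
    return PipelineConfig(
        synthetic=SyntheticConfig(seed=seed),
        train_years=(2016, 2017, 2018, 2019),
        test_years=(2020, 2021),
        seed=seed,
    )
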
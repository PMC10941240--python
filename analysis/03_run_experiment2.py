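"""Full synthetic Experiment 2: gap-evoked microsaccadic inhibition.

Same paradigm with the task significance of steps and gaps swapped (step
targets, task-irrelevant gaps) and the deeper gap-evoked inhibition
(0.80/0.61 events/s attended/ignored). Writes results/exp2/.
"""

import argparse
import json
from pathlib import Path

from ocumsi.pipeline import run_pipeline, validate_config


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/exp2"))
    args = parser.parse_args()

    config = validate_config(
        {
            "experiment": 2,
            "seed": args.seed,
            "sim": {
                "msi_depth_attended": 0.80,
                "msi_depth_ignored": 0.61,
                "hit_probability": 0.981,
                "fa_probability": 0.007,
                "rt_median": 0.77,
            },
        }
    )
    metrics = run_pipeline(config, args.out)
    print(json.dumps(metrics, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
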
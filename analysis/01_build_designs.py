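"""Build the session designs for both experiments and summarize them.

Writes results/design_exp1.tsv and results/design_exp2.tsv (plus .meta
sidecars) and prints the trial composition — 128 trials in 4 blocks, with
8 behavioral-target trials per block and the 24/24/24/24 placement of the
task-irrelevant event across attended / ignored / both / neither streams.
"""

import argparse
from pathlib import Path

from ocumsi import design as dsg


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for experiment in (1, 2):
        session = dsg.build_session(experiment, args.seed)
        path = args.out / f"design_exp{experiment}.tsv"
        dsg.write_design(session, path)
        counts = session.condition_counts()
        target = "gap" if experiment == 1 else "step"
        print(f"Experiment {experiment}: {len(session)} trials -> {path}")
        print(f"  behavioral target: {target}")
        for condition in sorted(counts):
            print(f"  {condition:<16} {counts[condition]}")


if __name__ == "__main__":
    main()
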
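#!/usr/bin/env python
"""Train one wide network per subject along its trial log.

By default the two-stage (response-then-feedback) update couples each
network to its subject's recorded behaviour; ``--mode feedback`` trains
the classic stimulus-driven rule instead. Output: per-subject prediction
CSVs and final weight matrices under results/trained/.
"""

import argparse
from pathlib import Path

from widelex.learner import TrainMode
from widelex.pipeline import RunConfig, cmd_train

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--logs", type=Path, default=ROOT / "results" / "logs")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "trained")
    ap.add_argument("--mode", choices=["double", "feedback"], default="double")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    mode = TrainMode.DOUBLE if args.mode == "double" else TrainMode.FEEDBACK_ONLY
    cfg = RunConfig(seed=args.seed)
    logs = sorted(args.logs.glob("S*.csv"))
    if not logs:
        raise SystemExit(f"no trial logs under {args.logs}; run 01 first")
    for f in logs:
        cmd_train(f, cfg, mode, args.out)
        print(f"trained {mode.value} network on {f.name}")


if __name__ == "__main__":
    main()
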
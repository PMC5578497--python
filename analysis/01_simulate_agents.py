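#!/usr/bin/env python
"""Simulate the six synthetic subjects through staircase lexical-decision
schedules and write their trial logs.

Each subject gets its own schedule (words introduced incrementally against
one-shot nonwords) and its own attentional profile (nonword bias that
decays, block-wise lapse drift). Output: results/logs/S*.csv plus the cue
inventory and a manifest.
"""

import argparse
from pathlib import Path

from widelex.pipeline import RunConfig, ScheduleSpec, cmd_generate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--trials", type=int, default=10_000,
                    help="trials per subject (the full design uses 60,000)")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "logs")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed)
    cfg.schedule = ScheduleSpec(n_trials=args.trials)
    outputs = cmd_generate(cfg, args.out)
    print(f"wrote {len(outputs)} files under {args.out}")
    for f in sorted(args.out.glob("S*.csv")):
        n_lines = sum(1 for _ in open(f)) - 1
        print(f"  {f.name}: {n_lines} trials")


if __name__ == "__main__":
    main()
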
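#!/usr/bin/env python
"""Run the full study replica: every participant-side simulated twice
(before/after Casson parameters) on its own geometry with the shared
waveform, then summarized into study-style tables.

Profiles: 'smoke' (2 participants, one side, coarse mesh; minutes) and
'paper-scale' (8 participants, both sides = 16 arteries; hours).  All
stages re-derive their inputs deterministically from --seed, so this
script is self-contained.

Usage: python analysis/03_run_study.py [--profile smoke] [--seed 0]
                                       [--out results/study]
"""

import argparse

from hemoflow.pipeline import paper_scale_config, run_study, smoke_config


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--profile", choices=("smoke", "paper-scale"),
                    default="smoke")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()

    maker = smoke_config if args.profile == "smoke" else paper_scale_config
    cfg = maker(seed=args.seed) if args.out is None else \
        maker(outdir=args.out, seed=args.seed)
    manifest = run_study(cfg)
    print(f"Completed stages: {', '.join(manifest.stages)}")
    print(f"{len(manifest.file_hashes)} artifacts under {cfg.outdir} "
          f"({manifest.wall_seconds:.0f} s)")


if __name__ == "__main__":
    main()
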
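#!/usr/bin/env python
"""Generate a synthetic two-session experiment with known ground truth.

Writes trials.csv / meta.csv / trials.schema.json / truth.json under
results/synth/. The default here is a 4-participant, 2-block dataset to keep
the CSV small; pass --participants 16 --blocks 6 for the full published
design (the analysis drivers and tests stream it participant-by-participant
instead of writing it out).
"""

import argparse
from pathlib import Path

import pandas as pd

from reach_ofc.io import write_schema
from reach_ofc.synth import SynthConfig, ground_truth, iter_participants

OUT = Path(__file__).resolve().parents[1] / "results" / "synth"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--participants", type=int, default=4)
    ap.add_argument("--blocks", type=int, default=2)
    args = ap.parse_args()
    cfg = SynthConfig(n_participants=args.participants, n_blocks=args.blocks,
                      master_seed=args.seed)
    OUT.mkdir(parents=True, exist_ok=True)
    metas, first, cols = [], True, None
    n_rows = 0
    for samples, meta in iter_participants(cfg):
        samples.to_csv(OUT / "trials.csv", index=False,
                       mode="w" if first else "a", header=first)
        n_rows += len(samples)
        metas.append(meta)
        cols = samples.columns
        first = False
    meta = pd.concat(metas, ignore_index=True)
    meta.to_csv(OUT / "meta.csv", index=False)
    write_schema(OUT, cols, meta.columns, config_hash=f"synth-{args.seed}",
                 seed=args.seed)
    ground_truth(cfg).to_json(OUT / "truth.json")
    print(f"{len(meta)} trials ({(~meta['is_calibration']).sum()} regular), "
          f"{n_rows} samples -> {OUT}")


if __name__ == "__main__":
    main()
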
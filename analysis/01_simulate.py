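#!/usr/bin/env python
"""Generate the synthetic ciliate transcriptome study.

Writes the genome, the deliberately imperfect input annotation, per-sample
junction/coverage/count evidence, microarray probes and the full truth
tables under results/simdata/.  Everything downstream (02-05) consumes
this directory.
"""

import argparse
from pathlib import Path

from splicerefine.simulate import SimConfig, simulate_dataset, write_dataset


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--outdir", default="results/simdata")
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    ds = simulate_dataset(cfg)
    write_dataset(ds, args.outdir)

    t = ds.truth
    by_type = {}
    for e in t.events:
        by_type[e.event_type] = by_type.get(e.event_type, 0) + 1
    print(f"wrote study to {args.outdir}")
    print(f"  genes: {cfg.n_genes} on {cfg.n_scaffolds} x {cfg.scaffold_length/1e3:.0f} kb scaffolds")
    print(f"  planted AS events: {len(t.events)} {by_type}")
    print(f"  planted annotation defects: {len(t.boundary_defects)} boundary, "
          f"{len(t.intron_defects)} missing/extra intron, "
          f"{len(t.merged_defects)} wrongly merged, {len(t.split_defects)} wrongly split")
    print(f"  novel transcribed regions: {len(t.novels)} "
          f"({sum(1 for n in t.novels if n.length >= 300)} at >=300 bp)")
    print(f"  stage-up-regulated genes: { {k: len(v) for k, v in t.stage_up.items()} }")


if __name__ == "__main__":
    main()
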
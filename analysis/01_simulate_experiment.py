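#!/usr/bin/env python
"""Simulate the full artificial-selection experiment at study scale.

A 120-family base population from a circulant crossing design, then four
generations of disruptive correlational selection (PC2 extremes of family
means) in two replicate selection lines and random selection in a control
line, with only males measured.  Writes the pedigree, phenotypes and
per-generation selection differentials under results/.
"""

import argparse
from pathlib import Path

from gmatrixlab import ExperimentConfig, TraitModel, simulate_experiment

FLOAT_FMT = "%.6g"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = ExperimentConfig(seed=args.seed)
    model = TraitModel.default()
    res = simulate_experiment(cfg, model)

    res.pedigree.to_csv(args.out_dir / "pedigree.csv")
    res.phenotypes.to_csv(args.out_dir / "phenotypes.csv", index=False,
                          float_format=FLOAT_FMT)
    res.family_records.to_csv(args.out_dir / "selection_records.csv",
                              index=False, float_format=FLOAT_FMT)
    res.differentials.to_csv(args.out_dir / "selection_differentials.csv",
                             index=False, float_format=FLOAT_FMT)

    ph = res.phenotypes
    print(f"simulated {len(res.pedigree)} individuals "
          f"({int(ph['measured'].sum())} measured males)")
    print("\nselection differentials (PC2 units, per line x generation):")
    print(res.differentials.round(3).to_string(index=False))
    sel = res.differentials.query("line != 'control'")["disruptive_pc2"]
    print(f"\ndisruptive differential in selection lines: "
          f"min {sel.min():.2f}, mean {sel.mean():.2f} (all positive: "
          f"{(sel > 0).all()})")


if __name__ == "__main__":
    main()
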
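"""Determine each protein's unfolding transition and stable temperature range.

Reads the ThermoFluor profiles from results/inputs/, applies the
highest-mean-fluorescence transition rule and the one-grid-step-back stable
range, and writes results/stability_ranges.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from asgard_ogt import read_profiles, stable_range


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=str, default="results/inputs")
    parser.add_argument("--out", type=str, default="results/stability_ranges.tsv")
    args = parser.parse_args()

    rows = []
    for profile in read_profiles(Path(args.in_dir) / "stability.tsv", "stability"):
        sr = stable_range(profile)
        rows.append(
            {
                "protein_id": profile.protein_id,
                "t_transition": sr.t_transition,
                "stable_min": sr.stable_min,
                "stable_max": sr.stable_max,
            }
        )
    table = pd.DataFrame(rows).sort_values("protein_id")
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)

    print(table.to_string(index=False))
    print(f"\n{len(table)} stable ranges written to {args.out}")


if __name__ == "__main__":
    main()
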
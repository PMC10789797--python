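"""Map the OGT estimates onto the phylogeny and compute the trajectory.

Reads the tree from step 01 and the estimates from step 03, attaches each
estimate to its node, computes the calibration correlation between known
growth optima and measured binding optima, and emits the evolutionary
trajectory table (per-node OGT change relative to the nearest annotated
ancestor) plus a temperature-colored tree figure.
Writes results/trajectory.tsv, results/annotated_tree.nwk, results/tree.png.
"""

import argparse
from pathlib import Path

import pandas as pd

from asgard_ogt import OgtEstimate, annotate_nodes, pearson_r, trajectory_table, write_newick
from asgard_ogt.ogt import read_calibration_table
from asgard_ogt.trees import annotations_table, plot_tree, read_newick_file


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=str, default="results/inputs")
    parser.add_argument("--estimates", type=str, default="results/ogt_estimates.tsv")
    parser.add_argument("--out-dir", type=str, default="results")
    args = parser.parse_args()

    out = Path(args.out_dir)
    tree = read_newick_file(Path(args.in_dir) / "tree.nwk")
    table = pd.read_csv(args.estimates, sep="\t")
    estimates = [
        OgtEstimate(r.protein_id, r.t_star, r.ci_lower, r.ci_upper, r.lifestyle)
        for r in table.itertuples()
    ]
    tree = annotate_nodes(tree, estimates)

    (out / "annotated_tree.nwk").write_text(write_newick(tree, annotations=True))
    annotations_table(tree).to_csv(out / "tree_annotations.tsv", sep="\t", index=False)
    traj = trajectory_table(tree)
    traj.to_csv(out / "trajectory.tsv", sep="\t", index=False)
    plot_tree(tree, out / "tree.png")

    cal = pearson_r(read_calibration_table(Path(args.in_dir) / "calibration.tsv"))

    print(traj.to_string(index=False))
    root_ogt = tree.estimates["root"].ogt
    cooling = (traj["delta"] < 0).mean()
    print(f"\nroot OGT estimate {root_ogt:.1f} degC ({tree.estimates['root'].lifestyle})")
    print(f"{cooling:.0%} of branches decrease in OGT (trend toward cooler lifestyles)")
    print(f"calibration: Pearson r = {cal.r:.4f} over {cal.n} organisms")
    print(f"trajectory, annotated tree and figure written to {out}/")


if __name__ == "__main__":
    main()
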
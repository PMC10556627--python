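"""Regenerate the committed golden outputs for the end-to-end determinism test.

Run from the repository root:

    python scripts/make_golden.py

Writes the 12-peak fixture outputs under tests/golden/. The fixture inputs are
generated in a temporary directory (they are fully determined by the generator
seed); only the pipeline outputs are committed.
"""

import sys
import tempfile
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from chipdecay.cli_pipeline import PipelineConfig, run_pipeline  # noqa: E402
from chipdecay.synthetic_data import SimulationConfig, write_simulation  # noqa: E402

GOLDEN_SEED = 2024
GOLDEN_N_PEAKS = 12

COMPARED = [
    "fit_table.tsv",
    "annotation.tsv",
    "quartile_summary.tsv",
    "stats_report.tsv",
    "tukey_pairwise.tsv",
    "netseq_profile.tsv",
    "h3_profile_by_quartile.tsv",
    "h3_profile_by_occupancy.tsv",
]


def golden_sim_config() -> SimulationConfig:
    return SimulationConfig(seed=GOLDEN_SEED, n_peaks=GOLDEN_N_PEAKS, noise="negbin")


def run_fixture(outdir: Path) -> dict:
    with tempfile.TemporaryDirectory() as tmp:
        paths = write_simulation(Path(tmp) / "sim", golden_sim_config())
        config = PipelineConfig(
            sample_sheet=str(paths["sample_sheet"]),
            counts=str(paths["counts"]),
            summits=str(paths["summits"]),
            genes=str(paths["genes"]),
            chrom_sizes=str(paths["chrom_sizes"]),
            h3_track=str(paths["h3"]),
            netseq_track=str(paths["netseq"]),
            taf1_track=str(paths["taf1"]),
            transcripts=str(paths["transcripts"]),
            outdir=str(outdir),
            nbins=20,  # keep the committed profile tables small
            flank=100,
            seed=GOLDEN_SEED,
        )
        return run_pipeline(config)


def main():
    golden = REPO / "tests" / "golden"
    golden.mkdir(parents=True, exist_ok=True)
    run_fixture(golden)
    (golden / "run.log").unlink(missing_ok=True)  # timestamps live here; not golden
    for name in COMPARED:
        assert (golden / name).exists(), name
    print(f"wrote {len(COMPARED)} golden tables to {golden}")


if __name__ == "__main__":
    main()
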
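"""Call ROH at SNP lengths 45/70/95 and summarize homozygosity by population.

Finds the nesting every cohort must show: proportion of genome in ROH
declines as the calling length grows (ROH95 <= ROH70 <= ROH45), and overall
genomic homozygosity sits near two-thirds for a medium-density panel.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, ensure_dirs

from autozygome.genotype_io import read_plink
from autozygome.pipeline import _concat_datasets
from autozygome.roh import call_roh, homozygosity_summary


def main() -> None:
    ensure_dirs()
    if not (SCRATCH / "US_clean.ped").exists():
        import importlib

        importlib.import_module("02_qc_merge").main()
    combined = _concat_datasets(
        {pop: read_plink(SCRATCH / f"{pop}_clean") for pop in ("US", "AU")}
    )
    segments = {L: call_roh(combined, L) for L in (45, 70, 95)}
    summary = homozygosity_summary(combined, segments)
    by_pop = (
        summary.table.drop(columns="animal_id")
        .groupby("population")
        .agg(["mean", "std"])
        .round(4)
    )
    by_pop.to_csv(RESULTS / "03_homozygosity_by_population.tsv", sep="\t")
    print(by_pop.to_string())
    for L, segs in segments.items():
        print(f"L={L}: {len(segs)} segments")


if __name__ == "__main__":
    main()
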
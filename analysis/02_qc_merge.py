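"""Quality control each population, then merge onto the common SNP set.

Mirrors the within-population QC of medium-density cattle panels: samples
under 90% call rate out first, then SNPs at MAF < 0.01 or Hardy-Weinberg
chi-square p < 0.001.  Note that the HWE filter interacts with strong
autozygosity: SNPs inside the heavily planted regions are homozygosity-
distorted and a fraction of them is removed here, which is why the planted
regions are wider than the 45-SNP calling rule strictly needs.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, ensure_dirs

from autozygome.genotype_io import apply_qc, intersect_snps, read_plink, write_plink


def main() -> None:
    ensure_dirs()
    if not (SCRATCH / "US.ped").exists():
        import importlib

        importlib.import_module("01_simulate").main()
    rows = []
    cleaned = {}
    for pop in ("US", "AU"):
        data = read_plink(SCRATCH / pop)
        clean, report = apply_qc(data)
        cleaned[pop] = clean
        rows.append(
            {
                "population": pop,
                "samples_in": data.n_samples,
                "samples_removed": len(report.removed_samples),
                "snps_in": data.n_markers,
                "snps_removed_maf": (report.removed_snps["reason"] == "maf").sum(),
                "snps_removed_hwe": (report.removed_snps["reason"] == "hwe").sum(),
            }
        )
    merged = intersect_snps(list(cleaned.values()))
    for pop, data in zip(cleaned, merged):
        write_plink(data, SCRATCH / f"{pop}_clean", dialect="ped")
    summary = pd.DataFrame(rows)
    summary["snps_common"] = merged[0].n_markers
    summary.to_csv(RESULTS / "02_qc_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"common SNP set after QC: {merged[0].n_markers}")


if __name__ == "__main__":
    main()
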
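"""Contrast per-SNP ROH45 frequency between the populations and call
regions.

Per SNP: the 1-df chi-square on the 2x2 population-by-in-ROH table, plus a
pooled permutation p-value for the absolute frequency difference (B=1000
label shuffles).  Differential regions need >= 45 contiguous significant
SNPs (p < 0.001) spanning > 4 Mb; common high-autozygosity regions need
the same contiguity within every population's top 2.5% of ROH45 frequency.
The calls are compared against the planted truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import COMMON_REGION, DIFF_REGION, RESULTS, SCRATCH, SEED, ensure_dirs

from autozygome.differential import (
    call_common_high_regions,
    call_differential_regions,
    chisq_per_snp,
    permutation_threshold,
    roh45_frequency,
)
from autozygome.genotype_io import read_plink
from autozygome.pipeline import _concat_datasets
from autozygome.regions import regions_to_frame
from autozygome.roh import roh_status


def main() -> None:
    ensure_dirs()
    if not (SCRATCH / "US_clean.ped").exists():
        import importlib

        importlib.import_module("02_qc_merge").main()
    combined = _concat_datasets(
        {pop: read_plink(SCRATCH / f"{pop}_clean") for pop in ("US", "AU")}
    )
    status = roh_status(combined, 45)
    groups = combined.samples["population"].to_numpy()
    track = roh45_frequency(status, groups)
    chi2, p_chisq = chisq_per_snp(track, "US", "AU")
    perm = permutation_threshold(
        status, groups, "US", "AU", n_permutations=1000, seed=SEED + 50
    )
    diff_regions = call_differential_regions(
        perm.p_values, combined.markers, freq_diff=perm.observed
    )
    common_regions = call_common_high_regions(track, combined.markers)
    regions_to_frame(diff_regions).round(4).to_csv(
        RESULTS / "05_regions_differential.tsv", sep="\t", index=False
    )
    regions_to_frame(common_regions).round(4).to_csv(
        RESULTS / "05_regions_common_high.tsv", sep="\t", index=False
    )
    print(f"differential regions: {len(diff_regions)}")
    for r in diff_regions:
        overlap = r.start_bp < DIFF_REGION.end_bp and r.end_bp > DIFF_REGION.start_bp
        print(
            f"  chr{r.chromosome} {r.start_bp/1e6:.1f}-{r.end_bp/1e6:.1f} Mb, "
            f"{r.n_snps} SNPs, peak diff {r.peak_value:.2f} at {r.peak_bp/1e6:.1f} Mb"
            f" ({'matches plant' if overlap and r.chromosome == 1 else 'unexpected'})"
        )
    print(f"common high-autozygosity regions: {len(common_regions)}")
    # the differential region also qualifies as common-high whenever its
    # minor population's frequency still reaches that population's top 2.5%
    for r in common_regions:
        overlap = any(
            r.chromosome == q.chromosome
            and r.start_bp < q.end_bp
            and r.end_bp > q.start_bp
            for q in (COMMON_REGION, DIFF_REGION)
        )
        print(
            f"  chr{r.chromosome} {r.start_bp/1e6:.1f}-{r.end_bp/1e6:.1f} Mb, "
            f"{r.n_snps} SNPs ({'overlaps a planted region' if overlap else 'unexpected'})"
        )


if __name__ == "__main__":
    main()
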
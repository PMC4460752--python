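"""Generate the study cohorts and persist them with their truth tables.

Writes PLINK ped/map, phenotypes and pedigree for the two-population
cohort under scratch/ (bulk data) and the region-carrier truth table under
results/ (the reference every later driver is judged against).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import COHORT, RESULTS, SCRATCH, TREND_COHORT, ensure_dirs

from autozygome.genotype_io import write_pedigree, write_phenotypes, write_plink
from autozygome.pipeline import _concat_datasets
from autozygome.synthetic_data import (
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


def main() -> None:
    ensure_dirs()
    datasets, truth = simulate_genotypes(COHORT)
    for pop, data in datasets.items():
        write_plink(data, SCRATCH / pop, dialect="ped")
    combined = _concat_datasets(datasets)
    pheno = simulate_phenotypes(combined, truth, COHORT)
    write_phenotypes(pheno, SCRATCH / "phenotypes.tsv")
    ped = simulate_pedigree(COHORT, sample_ids=list(combined.samples["animal_id"]))
    write_pedigree(ped, SCRATCH / "pedigree.txt")
    truth.region_carriers.to_csv(
        RESULTS / "01_truth_region_carriers.tsv", sep="\t", index=False
    )

    trend_sets, trend_truth = simulate_genotypes(TREND_COHORT)
    write_plink(trend_sets["US"], SCRATCH / "trend_US", dialect="ped")
    # ped/map carries no birth year: persist sample metadata alongside
    trend_sets["US"].samples.to_csv(
        SCRATCH / "trend_US_samples.tsv", sep="\t", index=False
    )
    combined.samples.to_csv(SCRATCH / "samples.tsv", sep="\t", index=False)
    trend_truth.region_carriers.to_csv(
        RESULTS / "01_truth_trend_carriers.tsv", sep="\t", index=False
    )

    for pop, data in datasets.items():
        print(f"{pop}: {data.n_samples} animals x {data.n_markers} SNPs")
    print(f"{len(pheno)} lactation records, pedigree of {len(ped.animals)} animals")
    print("truth tables -> results/01_truth_*.tsv; data -> scratch/analysis/")


if __name__ == "__main__":
    main()
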
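"""Quantify differentiation between the two populations.

Builds the Yang GRM on the merged cohort, runs PCA (PC1 should separate
the population labels), and computes the 8-SNP moving-window
Weir-Cockerham F_ST track between the populations.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, ensure_dirs

from autozygome.genotype_io import read_plink
from autozygome.pipeline import _concat_datasets, _plot_pca
from autozygome.structure import build_grm, fst_windowed, pca


def main() -> None:
    ensure_dirs()
    if not (SCRATCH / "US_clean.ped").exists():
        import importlib

        importlib.import_module("02_qc_merge").main()
    datasets = {pop: read_plink(SCRATCH / f"{pop}_clean") for pop in ("US", "AU")}
    combined = _concat_datasets(datasets)
    grm = build_grm(combined)
    res = pca(grm)
    label = (combined.samples["population"] == "US").to_numpy(float)
    r = float(np.corrcoef(res.eigenvectors[:, 0], label)[0, 1])
    track = fst_windowed(datasets["US"], datasets["AU"], window_snps=8)
    summary = pd.DataFrame(
        [
            {
                "grm_mean_diagonal": float(np.mean(np.diag(grm.matrix))),
                "pc1_variance_fraction": float(res.variance_fraction[0]),
                "pc2_variance_fraction": float(res.variance_fraction[1]),
                "pc1_population_correlation": abs(r),
                "fst_mean_windowed": track.genome_mean,
                "fst_max_windowed": track.genome_max,
            }
        ]
    ).round(4)
    summary.to_csv(RESULTS / "04_structure_summary.tsv", sep="\t", index=False)
    scores = pd.DataFrame(
        {
            "animal_id": combined.samples["animal_id"],
            "population": combined.samples["population"],
            "PC1": res.eigenvectors[:, 0],
            "PC2": res.eigenvectors[:, 1],
        }
    )
    _plot_pca(scores, res, RESULTS / "04_pca.png")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
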
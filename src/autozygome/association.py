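"""Association of flagged regions with yield traits.

Pipeline: lactation records are adjusted per population by a fixed-effects
model (herd-year-season, parity, calving month, linear age at first
calving); a cow's yield deviation (YD) is the mean of her adjusted records,
standardized within population to mean 0 variance 1.  Each YD is weighted
by its information content following the Garrick et al. deregression
weight

    w(l) = (1 - h^2) / (h^2 + (1 + r^2 (l - 1)) / l - h^2)

with heritability h^2, repeatability r^2 and parity count l.  Per SNP, a
weighted single-marker animal model

    y = mu + pop + SNP * g + u + e/w ,   u ~ N(0, A sigma_u^2)

is solved through Henderson's mixed-model equations with the pedigree
numerator relationship matrix A and the variance ratio fixed from h^2
(lambda = sigma_e^2 / sigma_u^2 = (1 - h^2)/h^2).  Benjamini–Hochberg
q-values are computed per trait over the scanned SNP subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeDataset, Pedigree


def garrick_weight(l: int | np.ndarray, h2: float = 0.25, r2: float = 0.43):
    """Residual weight for a mean of ``l`` repeated records.

    w(1) = 1 - h2 (the bracket collapses to 1); increasing in l when
    r2 > h2; limit as l -> inf is (1-h2)/r2.
    """
    if not (0 < h2 <= r2 < 1):
        raise ValueError("need 0 < h2 <= r2 < 1")
    l_arr = np.asarray(l, dtype=float)
    if np.any(l_arr < 1):
        raise ValueError("parity count l must be >= 1")
    w = (1.0 - h2) / (h2 + (1.0 + r2 * (l_arr - 1.0)) / l_arr - h2)
    return w if isinstance(l, np.ndarray) else float(w)


@dataclass
class AMatrix:
    """Pedigree numerator relationship matrix (Wright's A), tabular method."""

    matrix: np.ndarray
    index: dict[str, int]

    def submatrix(self, animal_ids) -> np.ndarray:
        idx = [self.index[a] for a in animal_ids]
        return self.matrix[np.ix_(idx, idx)]


def build_a_matrix(pedigree: Pedigree) -> AMatrix:
    """Tabular method: a_ii = 1 + 0.5 * a(sire, dam);
    a_ij = 0.5 * (a_j,sire(i) + a_j,dam(i)) for j preceding i."""
    rec = pedigree.records
    animals = list(rec["animal_id"])
    index = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    A = np.zeros((n, n))
    sires = [index.get(s, -1) for s in rec["sire_id"]]
    dams = [index.get(d, -1) for d in rec["dam_id"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= i or d >= i:
            raise ValueError("pedigree not topologically ordered (or own ancestor)")
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if d >= 0:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return AMatrix(matrix=A, index=index)


@dataclass
class YieldDeviations:
    """Standardized mean adjusted records per cow and trait, with weights."""

    table: pd.DataFrame  # animal_id, population, trait, value, l, weight

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.table[self.table["trait"] == trait].reset_index(drop=True)


TRAITS = ("milk", "fat", "protein")


def yield_deviations(
    phenotypes: pd.DataFrame,
    populations: pd.Series | dict | None = None,
    traits=TRAITS,
    h2: float = 0.25,
    r2: float = 0.43,
) -> YieldDeviations:
    """Adjust lactation records for fixed environmental effects and reduce to
    one standardized yield deviation per cow and trait.

    Per population and trait: OLS on herd-year-season, parity and calving
    month (categorical) plus age at first calving (linear); residuals
    averaged per cow; standardized to mean 0, variance 1 within population.
    ``populations`` maps animal_id to population; if absent and the table
    has a ``population`` column it is used, else one population is assumed.
    """
    pheno = phenotypes.copy()
    if populations is not None:
        popmap = pd.Series(populations)
        pheno["population"] = pheno["animal_id"].map(popmap)
    elif "population" not in pheno.columns:
        pheno["population"] = "ALL"
    pheno["hys"] = (
        pheno["herd_id"].astype(str)
        + ":" + pheno["year"].astype(str)
        + ":" + pheno["season"].astype(str)
    )
    rows = []
    for pop, chunk in pheno.groupby("population"):
        for trait in traits:
            y = chunk[trait].to_numpy(dtype=float)
            X_parts = [np.ones((len(chunk), 1))]
            for col in ("hys", "parity", "month"):
                dummies = pd.get_dummies(chunk[col].astype(str), drop_first=True)
                if dummies.shape[1]:
                    X_parts.append(dummies.to_numpy(dtype=float))
            age = chunk["age"].to_numpy(dtype=float)
            X_parts.append((age - age.mean())[:, None])
            X = np.hstack(X_parts)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            per_cow = (
                pd.DataFrame({"animal_id": chunk["animal_id"].to_numpy(), "resid": resid})
                .groupby("animal_id")["resid"]
                .agg(["mean", "size"])
            )
            std = per_cow["mean"].std(ddof=0)
            if std == 0 or np.isnan(std):
                raise ValueError(f"degenerate yield deviations for {pop}/{trait}")
            value = (per_cow["mean"] - per_cow["mean"].mean()) / std
            for animal, v, l in zip(per_cow.index, value, per_cow["size"]):
                rows.append(
                    {
                        "animal_id": animal,
                        "population": pop,
                        "trait": trait,
                        "value": float(v),
                        "l": int(l),
                        "weight": garrick_weight(int(l), h2, r2),
                        "scale": float(std),  # pre-standardization SD
                    }
                )
    return YieldDeviations(table=pd.DataFrame(rows))


@dataclass
class AssociationResult:
    """Per SNP per trait: weighted mixed-model effect, SE, Wald p, BH q."""

    table: pd.DataFrame  # snp_id, chromosome, position_bp, trait, effect, se, p, q


def _mme_fit(y, X, A_sub, weights, lam, A_inv=None):
    """Henderson MME for y = X b + u + e/w, u ~ (0, A sigma_u^2),
    e ~ (0, diag(1/w) sigma_e^2), lambda = sigma_e^2/sigma_u^2 fixed.

    Returns (b_hat, cov_b_unscaled, sigma_e2_hat, dof).  One record per
    animal (Z = I).  ``A_inv`` may be precomputed for repeated fits."""
    n, p = X.shape
    W = np.asarray(weights, dtype=float)
    if A_inv is None:
        A_inv = np.linalg.inv(A_sub)
    XtW = X.T * W
    C = np.empty((p + n, p + n))
    C[:p, :p] = XtW @ X
    C[:p, p:] = XtW
    C[p:, :p] = XtW.T
    C[p:, p:] = lam * A_inv
    C[p:, p:].flat[:: n + 1] += W
    rhs = np.concatenate([XtW @ y, W * y])
    # one factorization serves both the solutions and the fixed-effect
    # block of the inverse coefficient matrix
    rhs_block = np.zeros((p + n, 1 + p))
    rhs_block[:, 0] = rhs
    rhs_block[:p, 1:] = np.eye(p)
    sol_block = np.linalg.solve(C, rhs_block)
    sol = sol_block[:, 0]
    b = sol[:p]
    cov_b = sol_block[:p, 1:]
    dof = n - np.linalg.matrix_rank(X)
    sse = float(y @ (W * y) - sol @ rhs)
    sigma_e2 = sse / dof if dof > 0 else np.nan
    return b, cov_b, sigma_e2, dof


def single_marker_scan(
    yd: YieldDeviations,
    genotypes: GenotypeDataset,
    A: AMatrix,
    snp_subset,
    h2: float = 0.25,
    traits=TRAITS,
) -> AssociationResult:
    """Weighted single-marker mixed-model scan over ``snp_subset``.

    Fixed effects: intercept, population; covariate: SNP dosage; random
    animal effect with covariance A sigma_u^2 and residual sigma_e^2 / w.
    The variance ratio is fixed at lambda = (1-h2)/h2; sigma_e^2 is
    profiled from the weighted residual sum of squares, and the Wald test
    uses a t reference with n - rank(X) degrees of freedom.  SNPs
    monomorphic in the phenotyped animals are reported with NaN effect and
    p = q = NaN.
    """
    lam = (1.0 - h2) / h2
    snp_idx = {s: i for i, s in enumerate(genotypes.markers["snp_id"])}
    missing_snps = [s for s in snp_subset if s not in snp_idx]
    if missing_snps:
        raise ValueError(f"SNPs not in genotypes: {missing_snps[:5]}...")
    geno_ids = {a: i for i, a in enumerate(genotypes.samples["animal_id"])}
    rows = []
    for trait in traits:
        sub = yd.for_trait(trait)
        sub = sub[sub["animal_id"].isin(geno_ids) & sub["animal_id"].isin(A.index)]
        if sub.empty:
            continue
        animals = list(sub["animal_id"])
        y = sub["value"].to_numpy(dtype=float)
        w = sub["weight"].to_numpy(dtype=float)
        pops = pd.get_dummies(sub["population"].astype(str), drop_first=True)
        X_base = np.hstack([np.ones((len(sub), 1)), pops.to_numpy(dtype=float)])
        A_sub = A.submatrix(animals)
        A_inv = np.linalg.inv(A_sub)
        g_rows = np.array([geno_ids[a] for a in animals])
        trait_rows = []
        for snp in snp_subset:
            j = snp_idx[snp]
            x = genotypes.calls[g_rows, j].astype(float)
            obs = x != MISSING
            x_fit = np.where(obs, x, x[obs].mean() if obs.any() else 0.0)
            if obs.sum() == 0 or np.ptp(x_fit) == 0:
                trait_rows.append((snp, np.nan, np.nan, np.nan))
                continue
            X = np.hstack([X_base, x_fit[:, None]])
            b, cov_b, s2, dof = _mme_fit(y, X, A_sub, w, lam, A_inv=A_inv)
            eff = b[-1]
            se = np.sqrt(cov_b[-1, -1] * s2)
            p = 2.0 * stats.t.sf(abs(eff / se), dof) if se > 0 else np.nan
            trait_rows.append((snp, eff, se, p))
        pvals = np.array([r[3] for r in trait_rows], dtype=float)
        qvals = np.full_like(pvals, np.nan)
        ok = np.isfinite(pvals)
        if ok.any():
            qvals[ok] = bh_fdr(pvals[ok])
        for (snp, eff, se, p), q in zip(trait_rows, qvals):
            j = snp_idx[snp]
            rows.append(
                {
                    "snp_id": snp,
                    "chromosome": int(genotypes.markers["chromosome"].iloc[j]),
                    "position_bp": int(genotypes.markers["position_bp"].iloc[j]),
                    "trait": trait,
                    "effect": eff,
                    "se": se,
                    "p": p,
                    "q": q,
                }
            )
    return AssociationResult(table=pd.DataFrame(rows))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the input
    order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
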
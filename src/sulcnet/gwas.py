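"""GWAS phenotype preparation, Nyholt thresholds and a minimal scan engine.

Phenotype preparation applies, in order: outlier exclusion at mean +/- 5 SD
(single pass), rank-based inverse normal transformation (Blom offset), and
OLS residualization on age, age^2, sex, age*sex, age^2*sex, site and Euler
number. The association engine is plain per-variant OLS with ancestry-PC
covariates, followed by greedy r^2 clumping and positional 10 kb
SNP-to-gene mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PreparedPhenotype",
    "MeffResult",
    "Thresholds",
    "prepare_phenotype",
    "rank_inverse_normal",
    "nyholt_meff",
    "significance_thresholds",
    "assoc_scan",
    "clump_leads",
    "map_snps_to_genes",
    "ancestry_pcs",
]


@dataclass(frozen=True)
class PreparedPhenotype:
    values: pd.Series  # residualized normal scores, included subjects only
    excluded: pd.Series  # subject -> reason, for excluded subjects
    n_excluded: int


@dataclass(frozen=True)
class MeffResult:
    m: int
    eigenvalues: np.ndarray = field(repr=False)
    meff_raw: float = 0.0
    meff: int = 0


@dataclass(frozen=True)
class Thresholds:
    snp_experiment: float
    snp_genome: float
    gene_experiment: float
    gene_genome: float


def rank_inverse_normal(values: pd.Series, offset: float = 3.0 / 8.0) -> pd.Series:
    """Rank-based inverse normal transform, Blom offset by default.

    x -> Phi^{-1}((rank - c) / (n + 1 - 2c)); average ranks for ties. The
    Blom variant (c = 3/8) gives denominator n + 1/4.
    """
    v = values.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError("missing values in phenotype")
    ranks = stats.rankdata(v, method="average")
    q = (ranks - offset) / (len(v) + 1.0 - 2.0 * offset)
    return pd.Series(stats.norm.ppf(q), index=values.index, name=values.name)


def _gwas_design(cov: pd.DataFrame) -> np.ndarray:
    """Intercept + age, age^2, sex, age*sex, age^2*sex, site dummies, EN."""
    age = pd.to_numeric(cov["age"]).to_numpy(dtype=float)
    sex = pd.to_numeric(cov["sex"]).to_numpy(dtype=float)
    en = pd.to_numeric(cov["EN"]).to_numpy(dtype=float)
    cols = [np.ones(len(cov)), age, age ** 2, sex, age * sex, age ** 2 * sex, en]
    site = pd.get_dummies(cov["site"].astype(str), prefix="site", drop_first=True)
    for c in site.columns:
        cols.append(site[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    return X


def prepare_phenotype(values: pd.Series, covariates: pd.DataFrame,
                      sd_limit: float = 5.0, rint_offset: float = 3.0 / 8.0,
                      min_subjects: int = 30) -> PreparedPhenotype:
    """Outlier exclusion, inverse-normal transform, covariate residualization.

    `values` are per-subject Fisher-Z complexity scores for one sulcus,
    indexed by subject; `covariates` has one row per subject with columns
    subject, age, sex, site, EN. Outlier bounds use the pre-exclusion mean
    and SD in a single pass.
    """
    v = values.astype(float)
    mu, sd = v.mean(), v.std(ddof=1)
    outlier = (v - mu).abs() > sd_limit * sd
    excluded = pd.Series("outlier_5sd", index=v.index[outlier])
    kept = v[~outlier]
    if len(kept) < min_subjects:
        raise ValueError(f"only {len(kept)} subjects remain after exclusion")
    z = rank_inverse_normal(kept, offset=rint_offset)
    cov = covariates.set_index("subject").loc[z.index]
    X = _gwas_design(cov)
    beta, _, _, _ = np.linalg.lstsq(X, z.to_numpy(), rcond=None)
    resid = pd.Series(z.to_numpy() - X @ beta, index=z.index, name=values.name)
    return PreparedPhenotype(values=resid, excluded=excluded,
                             n_excluded=int(outlier.sum()))


def nyholt_meff(phenotypes: pd.DataFrame) -> MeffResult:
    """Effective number of independent tests from eigenvalue variance.

    meff_raw = 1 + (M - 1) * (1 - Var(lambda)/M), with Var the sample
    variance (denominator M-1) of the eigenvalues of the phenotype
    correlation matrix; meff rounds half-to-even and is bounded to [1, M].
    """
    x = phenotypes.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 phenotypes")
    if np.isnan(x).any():
        raise ValueError("complete cases required")
    corr = np.corrcoef(x, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-8:
        import warnings

        warnings.warn("correlation matrix not positive semidefinite; "
                      "clipping negative eigenvalues at 0")
    lam = np.clip(lam, 0.0, None)
    m = x.shape[1]
    var = float(np.var(lam, ddof=1))
    meff_raw = 1.0 + (m - 1.0) * (1.0 - var / m)
    meff = int(min(max(round(meff_raw), 1), m))
    return MeffResult(m=m, eigenvalues=np.sort(lam)[::-1], meff_raw=meff_raw,
                      meff=meff)


def significance_thresholds(meff: int, n_genes: int = 19_299,
                            base_snp: float = 5e-8,
                            base_gene_alpha: float = 0.05) -> Thresholds:
    """Experiment- and genome-wide SNP and gene significance thresholds."""
    if meff < 1 or n_genes < 1:
        raise ValueError("meff and n_genes must be >= 1")
    return Thresholds(
        snp_experiment=base_snp / meff,
        snp_genome=base_snp,
        gene_experiment=base_gene_alpha / n_genes / meff,
        gene_genome=base_gene_alpha / n_genes,
    )


def ancestry_pcs(dosages: np.ndarray, k: int = 10) -> np.ndarray:
    """First k PCs of the column-centered dosage matrix (thin SVD helper)."""
    x = np.asarray(dosages, dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    return u[:, :k] * s[:k]


def assoc_scan(dosages: np.ndarray, variants: pd.DataFrame,
               phenotype: pd.Series, subjects,
               covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Per-variant additive-allele OLS scan.

    `phenotype` is indexed by subject and must align with `subjects` (the
    dosage row order). Covariates (e.g. ancestry PCs) are projected out of
    both phenotype and dosages (Frisch-Waugh), leaving per-variant simple
    regressions with the correct residual degrees of freedom. Monomorphic
    variants get NaN results.
    """
    subjects = list(subjects)
    if set(phenotype.index) != set(subjects):
        raise ValueError("phenotype subjects do not match genotype subjects")
    y = phenotype.loc[subjects].to_numpy(dtype=float)
    g = np.asarray(dosages, dtype=float)
    if g.shape[0] != len(subjects):
        raise ValueError("dosage rows do not match subjects")
    n = len(y)
    if covariates is None or covariates.size == 0:
        ncov = 0
        X = np.ones((n, 1))
    else:
        c = np.asarray(covariates, dtype=float)
        ncov = c.shape[1]
        X = np.column_stack([np.ones(n), c])
    # project out intercept + covariates
    q, _ = np.linalg.qr(X)
    yr = y - q @ (q.T @ y)
    gr = g - q @ (q.T @ g)

    dof = n - ncov - 2  # intercept + dosage + covariates
    gss = np.einsum("ij,ij->j", gr, gr)
    mono = (g.max(axis=0) - g.min(axis=0)) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (gr.T @ yr) / gss
        rss = yr @ yr - beta ** 2 * gss
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / gss)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    out = variants[["id", "chrom", "pos"]].copy()
    out["A1"] = variants["alt"] if "alt" in variants else "NA"
    out["beta"] = np.where(mono, np.nan, beta)
    out["se"] = np.where(mono, np.nan, se)
    out["p"] = np.where(mono, np.nan, p)
    out["n"] = n
    out["monomorphic"] = mono
    return out


def clump_leads(assoc: pd.DataFrame, dosages: np.ndarray,
                p_threshold: float, r2_threshold: float = 0.1) -> pd.DataFrame:
    """Greedy LD clumping of significant variants.

    Repeatedly takes the smallest-p significant variant as a lead and drops
    all significant variants with sample dosage r^2 >= `r2_threshold`
    against it. Ties in p break by (chromosome, position). Returns the lead
    rows of `assoc` in selection order.
    """
    sig = assoc[(assoc["p"].notna()) & (assoc["p"] < p_threshold)].copy()
    if sig.empty:
        return sig
    sig["_order"] = np.arange(len(sig))
    sig = sig.sort_values(["p", "chrom", "pos"], kind="mergesort")
    g = np.asarray(dosages, dtype=float)
    active = list(sig.index)
    leads = []
    while active:
        lead = active[0]
        leads.append(lead)
        gl = g[:, assoc.index.get_loc(lead)]
        keep = []
        for idx in active[1:]:
            gv = g[:, assoc.index.get_loc(idx)]
            if np.ptp(gl) == 0 or np.ptp(gv) == 0:
                r2 = 1.0  # monomorphic against lead: treat as fully linked
            else:
                r2 = float(np.corrcoef(gl, gv)[0, 1] ** 2)
            if r2 < r2_threshold:
                keep.append(idx)
        active = keep
    return assoc.loc[leads].copy()


def map_snps_to_genes(leads: pd.DataFrame, genes: pd.DataFrame,
                      window: int = 10_000) -> pd.DataFrame:
    """Positional SNP-to-gene mapping within a symmetric window.

    `genes` has 1-based inclusive columns gene, chrom, start, end. A gene is
    a hit iff the variant position lies in [start - window, end + window];
    intragenic hits have distance 0.
    """
    if (genes["end"] < genes["start"]).any():
        raise ValueError("malformed gene intervals (end < start)")
    rows = []
    for _, snp in leads.iterrows():
        cand = genes[genes["chrom"].astype(str) == str(snp["chrom"])]
        pos = int(snp["pos"])
        for _, gene in cand.iterrows():
            if gene["start"] - window <= pos <= gene["end"] + window:
                if pos < gene["start"]:
                    dist = int(gene["start"] - pos)
                elif pos > gene["end"]:
                    dist = int(pos - gene["end"])
                else:
                    dist = 0
                rows.append({"id": snp["id"], "chrom": snp["chrom"], "pos": pos,
                             "gene": gene["gene"], "distance": dist})
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "gene", "distance"])
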
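"""Fetal spatiotemporal expression modules and preranked GSEA.

Genes are clustered by their Z-scored (within timepoint) expression over
region x layer x timepoint cells; k is chosen by an elbow criterion on the
within/between sum-of-squares ratio; each module gets a degree-weighted
prototype profile; the transcriptome is ranked by co-expression with each
prototype and scored with a weighted Kolmogorov-Smirnov enrichment
statistic against gene sets, with sign-stratified permutation p and FDR q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModuleResult",
    "GseaResult",
    "zscore_by_timepoint",
    "flatten_profiles",
    "kmeans_sweep",
    "elbow_select",
    "module_prototypes",
    "coexpression_ranking",
    "gsea_preranked",
    "fit_modules",
]

_CUBE_KEYS = ["gene", "region", "layer", "timepoint"]


def _check_cube(cube: pd.DataFrame) -> None:
    missing = [c for c in _CUBE_KEYS + ["value"] if c not in cube.columns]
    if missing:
        raise ValueError(f"expression cube is missing columns {missing}")
    counts = cube.groupby("gene", observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("incomplete (region, layer, timepoint) crossing per gene")


def zscore_by_timepoint(cube: pd.DataFrame) -> pd.DataFrame:
    """Standardize each (gene, timepoint) slice across its region x layer cells.

    Standard deviation uses the n-1 denominator; a constant slice is an
    error naming the gene and timepoint.
    """
    _check_cube(cube)
    out = cube.copy()
    grouped = out.groupby(["gene", "timepoint"], observed=True)["value"]
    mean = grouped.transform("mean")
    sd = grouped.transform(lambda s: s.std(ddof=1))
    bad = sd.isna() | (sd == 0)
    if bad.any():
        row = out[bad].iloc[0]
        raise ValueError(
            f"constant expression slice for gene {row['gene']!r} "
            f"at timepoint {row['timepoint']!r}"
        )
    out["value"] = (out["value"] - mean) / sd
    return out


def flatten_profiles(cube: pd.DataFrame, regions=None, layers=None,
                     timepoints=None) -> pd.DataFrame:
    """Genes x (regions * layers * timepoints) profile matrix.

    Column order is timepoint-major, then layer, then region; column labels
    encode the cell as ``"{timepoint}|{layer}|{region}"``.
    """
    _check_cube(cube)
    regions = list(regions) if regions is not None else sorted(cube["region"].unique())
    layers = list(layers) if layers is not None else sorted(cube["layer"].unique())
    timepoints = (list(timepoints) if timepoints is not None
                  else sorted(cube["timepoint"].unique()))
    wide = cube.pivot_table(index="gene", columns=["timepoint", "layer", "region"],
                            values="value", aggfunc="first")
    cols = [(t, l, r) for t in timepoints for l in layers for r in regions]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    if wide.isna().any().any():
        raise ValueError("incomplete expression cube")
    wide.columns = [f"{t}|{l}|{r}" for t, l, r in cols]
    return wide


def unflatten_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`flatten_profiles` back to the long cube layout."""
    parts = [c.split("|") for c in profiles.columns]
    long = profiles.stack().rename("value").reset_index()
    long.columns = ["gene", "cell", "value"]
    decoded = pd.DataFrame(parts, columns=["timepoint", "layer", "region"])
    decoded["cell"] = list(profiles.columns)
    out = long.merge(decoded, on="cell").drop(columns="cell")
    return out[["gene", "region", "layer", "timepoint", "value"]]


def kmeans_sweep(profiles: pd.DataFrame, k_min: int = 2, k_max: int | None = None,
                 restarts: int = 50, seed: int = 0):
    """Best-of-restarts k-means for each k; within/between SS ratio per k.

    Returns ``(assignments, ratios)``: a genes x k frame of labels and a
    Series of within/between SS ratios indexed by k. k_max defaults to
    n_genes // 2.
    """
    from sklearn.cluster import KMeans

    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 genes")
    if k_max is None:
        k_max = n // 2
    k_max = min(k_max, n - 1)
    if k_max < k_min:
        raise ValueError("k_max < k_min")
    total_ss = float(((x - x.mean(axis=0)) ** 2).sum())
    labels = {}
    ratios = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=restarts, init="k-means++",
                    random_state=seed).fit(x)
        within = float(km.inertia_)
        between = total_ss - within
        ratios[k] = within / between if between > 0 else np.inf
        labels[k] = km.labels_ + 1
    assignments = pd.DataFrame(labels, index=profiles.index)
    return assignments, pd.Series(ratios, name="ss_ratio").sort_index()


def elbow_select(ratios: pd.Series) -> int:
    """k with the greatest discrete curvature of the SS-ratio curve.

    Maximizes ratio(k-1) - 2*ratio(k) + ratio(k+1) over interior k; ties go
    to the smallest k. If the curve is exactly linear (zero curvature
    everywhere) the smallest k is returned with a warning.
    """
    r = ratios.sort_index()
    if len(r) < 3:
        raise ValueError("need at least 3 k values for the elbow criterion")
    ks = r.index.to_numpy()
    v = r.to_numpy(dtype=float)
    curv = v[:-2] - 2.0 * v[1:-1] + v[2:]
    if np.allclose(curv, 0.0, atol=1e-12):
        warnings.warn("SS-ratio curve has no curvature; returning k_min")
        return int(ks[0])
    return int(ks[1:-1][int(np.argmax(curv))])


@dataclass(frozen=True)
class ModuleResult:
    k_selected: int
    labels: pd.Series  # gene -> module id (1..k)
    ratios: pd.Series  # per-k within/between SS ratio
    degrees: pd.Series  # gene -> degree
    prototypes: pd.DataFrame  # module x profile cells


def module_prototypes(profiles: pd.DataFrame, labels: pd.Series,
                      clip_negative: bool = True):
    """Degree-weighted module prototypes.

    Degree of a gene = sum over same-module co-members of its profile
    correlation, positively clipped by default (``clip_negative=False``
    uses raw correlations). A singleton module's gene has degree 1. The
    prototype is the degree-weighted mean of member profiles (uniform
    fallback when all degrees are 0).
    """
    labels = labels.loc[profiles.index]
    degrees = pd.Series(0.0, index=profiles.index)
    protos = {}
    for module, members in labels.groupby(labels):
        idx = members.index
        block = profiles.loc[idx].to_numpy(dtype=float)
        if np.any(np.ptp(block, axis=1) == 0):
            raise ValueError(f"constant gene profile in module {module}")
        if len(idx) == 1:
            degrees.loc[idx] = 1.0
            w = np.array([1.0])
        else:
            c = np.corrcoef(block)
            np.fill_diagonal(c, 0.0)
            if clip_negative:
                c = np.clip(c, 0.0, None)
            d = c.sum(axis=1)
            degrees.loc[idx] = d
            w = d if d.sum() > 0 else np.ones(len(idx))
        protos[module] = (w[:, None] * block).sum(axis=0) / w.sum()
    prototypes = pd.DataFrame(protos, index=profiles.columns).T
    prototypes.index.name = "module"
    return degrees, prototypes


def fit_modules(profiles: pd.DataFrame, k_min: int = 2, k_max: int | None = None,
                restarts: int = 50, seed: int = 0,
                clip_negative: bool = True) -> ModuleResult:
    """Full module pipeline: sweep, elbow selection, prototypes."""
    assignments, ratios = kmeans_sweep(profiles, k_min=k_min, k_max=k_max,
                                       restarts=restarts, seed=seed)
    if len(ratios) >= 3:
        k = elbow_select(ratios)
    else:
        k = int(ratios.index[0])
    labels = assignments[k].rename("module")
    degrees, prototypes = module_prototypes(profiles, labels,
                                            clip_negative=clip_negative)
    return ModuleResult(k_selected=k, labels=labels, ratios=ratios,
                        degrees=degrees, prototypes=prototypes)


def coexpression_ranking(prototype: pd.Series | np.ndarray,
                         profiles: pd.DataFrame) -> pd.Series:
    """Rank all genes by profile correlation with a module prototype.

    Returns a Series of scores sorted descending (ties broken by gene id);
    constant gene profiles score NaN and sort last.
    """
    proto = np.asarray(prototype, dtype=float)
    if np.ptp(proto) == 0:
        raise ValueError("constant prototype")
    x = profiles.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    pc = proto - proto.mean()
    norms = np.linalg.norm(xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (xc @ pc) / (norms * np.linalg.norm(pc))
    scores = pd.Series(scores, index=profiles.index, name="score")
    scores = scores.iloc[np.lexsort((scores.index, -scores.fillna(-2).to_numpy()))]
    return scores


@dataclass(frozen=True)
class GseaResult:
    table: pd.DataFrame  # gene_set, size, es, nes, p, q
    null_es: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def _enrichment_score(order: np.ndarray, weights: np.ndarray,
                      hit_mask: np.ndarray) -> float:
    """Weighted KS running-sum ES for one set given a ranking."""
    n = len(order)
    nh = int(hit_mask.sum())
    w = weights[hit_mask]
    wsum = w.sum()
    steps = np.where(hit_mask, 0.0, -1.0 / (n - nh))
    if wsum > 0:
        steps = steps + np.where(hit_mask, weights / wsum, 0.0)
    else:  # all hit weights zero (e.g. weight>0 with zero scores): uniform
        steps = steps + np.where(hit_mask, 1.0 / nh, 0.0)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(ranked_scores: pd.Series, gene_sets: dict[str, list[str]],
                   weight: float = 1.0, n_perm: int = 1000, seed: int = 0,
                   min_size: int = 2, max_size: int = 5000) -> GseaResult:
    """Preranked GSEA with gene-label permutations.

    `ranked_scores` is gene -> score, sorted descending. Genes absent from
    the ranking are dropped from each set; sets outside [min_size, max_size]
    after filtering are errors. p values are sign-matched (positive ES
    against positive nulls and vice versa, add-one estimator); NES divides
    ES by the mean |same-sign null ES|; FDR q uses the sign-stratified
    ratio-of-tails over normalized null scores.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if ranked_scores.index.has_duplicates:
        raise ValueError("duplicate gene ids in ranking")
    genes = ranked_scores.index.to_numpy()
    scores = ranked_scores.to_numpy(dtype=float)
    valid = ~np.isnan(scores)
    genes, scores = genes[valid], scores[valid]
    n = len(genes)
    weights = np.abs(scores) ** weight
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    rows = []
    null_store: dict[str, np.ndarray] = {}
    all_null_nes: list[np.ndarray] = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in gene_pos]
        if not present:
            raise ValueError(f"gene set {name!r} empty after filtering")
        nh = len(set(present))
        if not (min_size <= nh <= max_size):
            raise ValueError(f"gene set {name!r} has size {nh} outside "
                             f"[{min_size}, {max_size}]")
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in set(present)]] = True
        es = _enrichment_score(np.arange(n), weights, mask)

        null = np.empty(n_perm)
        for b in range(n_perm):
            pmask = np.zeros(n, dtype=bool)
            pmask[rng.choice(n, size=nh, replace=False)] = True
            null[b] = _enrichment_score(np.arange(n), weights, pmask)
        null_store[name] = null

        pos = null[null >= 0]
        neg = null[null < 0]
        if es >= 0:
            p = (1 + int((pos >= es).sum())) / (1 + len(pos)) if len(pos) else 1.0
            denom = pos.mean() if len(pos) else np.nan
        else:
            p = (1 + int((neg <= es).sum())) / (1 + len(neg)) if len(neg) else 1.0
            denom = -neg.mean() if len(neg) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            pos_mean = pos.mean() if len(pos) else np.nan
            neg_mean = -neg.mean() if len(neg) else np.nan
            null_nes = np.where(null >= 0,
                                null / pos_mean if np.isfinite(pos_mean) else np.nan,
                                null / neg_mean if np.isfinite(neg_mean) else np.nan)
        all_null_nes.append(null_nes[np.isfinite(null_nes)])
        rows.append({"gene_set": name, "size": nh, "es": es, "nes": nes, "p": p})

    table = pd.DataFrame(rows)
    pooled = np.concatenate(all_null_nes) if all_null_nes else np.array([])
    obs = table["nes"].to_numpy()
    qs = []
    for nes in obs:
        if not np.isfinite(nes):
            qs.append(np.nan)
            continue
        if nes >= 0:
            null_tail = float((pooled >= nes).sum()) / max(1, (pooled >= 0).sum())
            obs_tail = float((obs[np.isfinite(obs)] >= nes).sum()) / max(
                1, (obs[np.isfinite(obs)] >= 0).sum())
        else:
            null_tail = float((pooled <= nes).sum()) / max(1, (pooled < 0).sum())
            obs_tail = float((obs[np.isfinite(obs)] <= nes).sum()) / max(
                1, (obs[np.isfinite(obs)] < 0).sum())
        qs.append(min(1.0, null_tail / obs_tail) if obs_tail > 0 else np.nan)
    table["q"] = qs
    return GseaResult(table=table, null_es=null_store)
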
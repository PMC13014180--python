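"""Spatial statistics on sulcus-level maps: spin nulls, similarity, PCA.

The spin null rotates the left-hemisphere parcel centroids by a uniform
random rotation (and the right hemisphere by its x-mirrored twin), reassigns
each parcel the map value of the nearest rotated centroid within its
hemisphere, and recomputes the cross-map correlation. p values use the
add-one permutation estimator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "SpinResult",
    "DeltaPCResult",
    "spatial_correlation",
    "spin_null",
    "congruence_profile",
    "cross_syndrome_similarity",
    "delta_pca",
    "random_rotations",
]

_MIRROR_X = np.diag([-1.0, 1.0, 1.0])


def _as_map(m) -> pd.Series:
    s = pd.Series(m) if not isinstance(m, pd.Series) else m
    v = s.to_numpy(dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("map contains non-finite values")
    return s.astype(float)


def spatial_correlation(a, b) -> float:
    """Pearson correlation of two sulcus maps over their shared order."""
    sa, sb = _as_map(a), _as_map(b)
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if set(sa.index) != set(sb.index):
            raise ValueError("maps cover different sulci")
        sb = sb.reindex(sa.index)
    va, vb = sa.to_numpy(), sb.to_numpy()
    if va.shape != vb.shape:
        raise ValueError("maps have different lengths")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant map; correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """`n` rotation matrices drawn uniformly (Haar) from SO(3)."""
    return Rotation.random(n, rng=rng).as_matrix()


def _spin_assignments(parcellation: pd.DataFrame, rotations: np.ndarray) -> np.ndarray:
    """Donor index per (spin, parcel): nearest rotated centroid, per hemisphere.

    Donors may repeat (sampling with replacement semantics).
    """
    n_parcels = len(parcellation)
    coords = parcellation[["x", "y", "z"]].to_numpy(dtype=float)
    hemis = parcellation["hemisphere"].to_numpy()
    out = np.empty((len(rotations), n_parcels), dtype=np.intp)
    for hemi in np.unique(hemis):
        sel = np.flatnonzero(hemis == hemi)
        c = coords[sel]
        rots = rotations if hemi == "L" else _MIRROR_X @ rotations @ _MIRROR_X
        # rotated[s, i, :] = rots[s] @ c[i]
        rotated = np.einsum("sab,ib->sia", rots, c)
        # nearest rotated centroid to each original centroid = max dot product
        dots = np.einsum("sia,ja->sji", rotated, c)
        out[:, sel] = sel[np.argmax(dots, axis=2)]
    return out


@dataclass(frozen=True)
class SpinResult:
    r_obs: float
    p_spin: float
    null: np.ndarray = field(repr=False)
    n_spins: int = 0
    sidedness: str = "two-sided"


def spin_null(parcellation: pd.DataFrame, map_a, map_b, n_spins: int = 10_000,
              seed: int = 0, sidedness: str = "two-sided",
              _rotations: np.ndarray | None = None) -> SpinResult:
    """Spin-based spatial permutation test for the correlation of two maps.

    `_rotations` is a test hook overriding the random rotations. The
    two-sided p uses absolute-value exceedance with the add-one estimator
    p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_spins).
    """
    if _rotations is None and n_spins < 100:
        raise ValueError("n_spins must be >= 100")
    order = list(parcellation["sulcus"])
    sa = _as_map(map_a).reindex(order)
    sb = _as_map(map_b).reindex(order)
    if sa.isna().any() or sb.isna().any():
        raise ValueError("parcellation does not cover both maps")
    va, vb = sa.to_numpy(), sb.to_numpy()
    r_obs = spatial_correlation(va, vb)

    rng = np.random.default_rng(seed)
    rotations = random_rotations(n_spins, rng) if _rotations is None else _rotations
    donors = _spin_assignments(parcellation, rotations)
    spun = va[donors]  # (spins, parcels)

    sc = spun - spun.mean(axis=1, keepdims=True)
    sd = sc.std(axis=1)
    vbc = vb - vb.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        null = (sc @ vbc) / (len(vb) * sd * vb.std())
    null = np.where(sd == 0, 0.0, null)

    if sidedness == "two-sided":
        exceed = np.abs(null) >= abs(r_obs) - 1e-12
    elif sidedness == "greater":
        exceed = null >= r_obs - 1e-12
    elif sidedness == "less":
        exceed = null <= r_obs + 1e-12
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p = float((1 + int(exceed.sum())) / (1 + len(null)))
    return SpinResult(r_obs=r_obs, p_spin=p, null=null, n_spins=len(null),
                      sidedness=sidedness)


def congruence_profile(phenotype_maps: dict[str, dict[str, pd.Series]],
                       delta_maps: dict[str, pd.Series],
                       parcellation: pd.DataFrame, n_spins: int = 10_000,
                       seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Spatial congruence of each phenotype's effect map with delta-complexity.

    `phenotype_maps[syndrome][phenotype]` and `delta_maps[syndrome]` are
    sulcus maps. Bonferroni flags correct across syndromes (alpha / n_syndromes)
    within each phenotype.
    """
    n_syn = len(delta_maps)
    rows = []
    for si, (syndrome, delta) in enumerate(delta_maps.items()):
        for pi, (phen, pmap) in enumerate(phenotype_maps[syndrome].items()):
            res = spin_null(parcellation, pmap, delta, n_spins=n_spins,
                            seed=seed + 7919 * si + 104729 * pi)
            rows.append({"syndrome": syndrome, "phenotype": phen,
                         "r": res.r_obs, "p_spin": res.p_spin})
    out = pd.DataFrame(rows)
    out["bonferroni"] = out["p_spin"] < alpha / n_syn
    out["nominal"] = out["p_spin"] < alpha
    return out


@dataclass(frozen=True)
class DeltaPCResult:
    sulci: tuple[str, ...]
    syndromes: tuple[str, ...]
    scores: np.ndarray = field(repr=False)  # sulci x components
    loadings: np.ndarray = field(repr=False)  # syndromes x components, in [-1,1]
    variance_explained: np.ndarray = field(repr=False)
    p_perm: np.ndarray = field(repr=False)

    def score_map(self, component: int = 0) -> pd.Series:
        return pd.Series(self.scores[:, component], index=list(self.sulci),
                         name=f"PC{component + 1}")

    def loading_series(self, component: int = 0) -> pd.Series:
        return pd.Series(self.loadings[:, component], index=list(self.syndromes),
                         name=f"PC{component + 1}")


def _pca_ve(y: np.ndarray) -> np.ndarray:
    s = np.linalg.svd(y - y.mean(axis=0, keepdims=True), compute_uv=False)
    tot = np.sum(s ** 2)
    if tot == 0:
        raise ValueError("degenerate (constant) input matrix")
    return s ** 2 / tot


def delta_pca(maps: pd.DataFrame, n_perm: int = 1000, seed: int = 0) -> DeltaPCResult:
    """PCA of delta-complexity maps with permutation significance.

    `maps` is syndromes x sulci. Sulci act as observations and syndromes as
    variables; each syndrome's map is centered. Per-component p values come
    from independently permuting each syndrome's map across sulci `n_perm`
    times and comparing variance-explained fractions (add-one estimator).
    Loadings are scaled by their per-component max |loading|, and each
    component's sign is set so its top-loading syndrome loads positively.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if maps.shape[0] < 1 or maps.shape[1] < 3:
        raise ValueError("need >= 1 syndromes and >= 3 sulci")
    syndromes = tuple(str(s) for s in maps.index)
    sulci = tuple(str(s) for s in maps.columns)
    y = maps.to_numpy(dtype=float).T  # sulci x syndromes
    yc = y - y.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    ve = s ** 2 / np.sum(s ** 2)
    scores = u * s  # sulci x comps
    loadings = vt.T  # syndromes x comps

    # orient: top-loading syndrome positive per component
    for j in range(loadings.shape[1]):
        top = np.argmax(np.abs(loadings[:, j]))
        if loadings[top, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    maxabs = np.max(np.abs(loadings), axis=0)
    maxabs[maxabs == 0] = 1.0
    loadings_scaled = loadings / maxabs

    rng = np.random.default_rng(seed)
    n_comp = len(ve)
    exceed = np.zeros(n_comp, dtype=int)
    for _ in range(n_perm):
        perm = np.empty_like(y)
        for j in range(y.shape[1]):
            perm[:, j] = y[rng.permutation(y.shape[0]), j]
        exceed += _pca_ve(perm)[:n_comp] >= ve - 1e-15
    p = (1 + exceed) / (1 + n_perm)
    return DeltaPCResult(sulci=sulci, syndromes=syndromes, scores=scores,
                         loadings=loadings_scaled, variance_explained=ve,
                         p_perm=p)


def cross_syndrome_similarity(maps: pd.DataFrame, n_perm: int = 1000,
                              seed: int = 0) -> pd.DataFrame:
    """Syndrome x syndrome spatial correlation matrix, ordered by PC1 loading.

    `maps` is syndromes x sulci. Rows/columns are sorted by descending PC1
    loading from :func:`delta_pca`.
    """
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 maps")
    names = list(maps.index)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = spatial_correlation(maps.loc[a], maps.loc[b])
            mat.loc[a, b] = mat.loc[b, a] = r
    pc = delta_pca(maps, n_perm=max(100, n_perm), seed=seed)
    order = pc.loading_series(0).sort_values(ascending=False).index
    return mat.loc[order, order]
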
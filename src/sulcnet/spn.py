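"""Sulcal phenotype networks (SPNs) and eigen-fold complexity scoring.

An SPN is a per-subject sulcus x sulcus correlation matrix of five
standardized shape phenotypes. The first principal component of a mean
control SPN (the eigen-fold index) orders sulci along the linear-to-complex
axis; a subject's per-sulcus complexity score is the Fisher-Z transformed
correlation of that sulcus's SPN row with the eigen-fold index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._atlas import CORE_PHENOTYPES, most_linear_sulcus

__all__ = [
    "SPN",
    "EigenFoldIndex",
    "zscore_within_subject",
    "build_spn",
    "mean_spn",
    "eigen_fold_index",
    "complexity_scores",
    "cross_reference_complexity",
    "spn_similarity",
    "bipartite_classes",
    "subject_spns",
    "fisher_z",
]

_CLIP = 1.0 - 1e-12


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher Z transform with |r| clipped to 1 - 1e-12 (never infinite)."""
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


@dataclass(frozen=True)
class SPN:
    """Symmetric sulcus x sulcus correlation matrix with unit diagonal."""

    sulci: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.sulci), len(self.sulci)):
            raise ValueError("SPN matrix shape does not match sulcus labels")
        if not np.all(np.isfinite(m)):
            raise ValueError("SPN entries must be finite")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("SPN must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("SPN diagonal must be 1")
        if m.min() < -1 - 1e-10 or m.max() > 1 + 1e-10:
            raise ValueError("SPN entries must lie in [-1, 1]")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.sulci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.sulci), columns=list(self.sulci))


@dataclass(frozen=True)
class EigenFoldIndex:
    """First principal component of a mean SPN: the linear-to-complex axis."""

    sulci: tuple[str, ...]
    scores: np.ndarray = field(repr=False)
    explained_variance: float = 0.0
    anchor: str | None = None

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.sulci), name="eigen_fold")


def zscore_within_subject(values: pd.DataFrame, phenotypes=CORE_PHENOTYPES,
                          subject: str = "?") -> pd.DataFrame:
    """Z-score each phenotype column across sulci within one subject.

    `values` is a sulci x phenotypes frame (one subject). Standardization
    uses the n-1 denominator. A zero-variance column is a hard error naming
    the subject and phenotype.
    """
    cols = [p for p in phenotypes if p in values.columns]
    if len(cols) != len(phenotypes):
        missing = set(phenotypes) - set(values.columns)
        raise ValueError(f"subject {subject}: missing phenotype columns {sorted(missing)}")
    x = values[list(cols)].astype(float)
    if x.isna().any().any():
        raise ValueError(f"subject {subject}: NaN phenotype values")
    sd = x.std(ddof=1)
    for p, s in sd.items():
        if not np.isfinite(s) or s == 0:
            raise ValueError(
                f"subject {subject}: phenotype {p!r} has zero variance across sulci"
            )
    return (x - x.mean()) / sd


def _row_correlations(z: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between rows of `z`."""
    zc = z - z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(zc, axis=1)
    if np.any(norms == 0):
        bad = int(np.argmin(norms))
        raise ValueError(f"sulcus row {bad} has a constant phenotype profile")
    zc /= norms[:, None]
    c = zc @ zc.T
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return 0.5 * (c + c.T)


def build_spn(z: pd.DataFrame) -> SPN:
    """Correlate each pair of sulci's standardized phenotype profiles.

    `z` is the output of :func:`zscore_within_subject` (sulci x phenotypes).
    """
    m = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("standardized matrix must be finite")
    if m.shape[1] < 2:
        raise ValueError("need at least 2 phenotypes to correlate")
    return SPN(tuple(str(s) for s in z.index), _row_correlations(m))


def subject_spns(table: pd.DataFrame, sulci, phenotypes=CORE_PHENOTYPES) -> dict[str, SPN]:
    """Build one SPN per subject from a long-format phenotype table.

    `table` must have columns subject, sulcus, phenotype, value. Sulcus
    rows are ordered by `sulci`.
    """
    sulci = list(sulci)
    wide = table.pivot_table(index=["subject", "sulcus"], columns="phenotype",
                             values="value", aggfunc="first")
    out: dict[str, SPN] = {}
    for subj, grp in wide.groupby(level="subject", sort=False):
        block = grp.droplevel("subject").reindex(sulci)
        if block.isna().any().any():
            raise ValueError(f"subject {subj}: incomplete sulcus x phenotype grid")
        z = zscore_within_subject(block, phenotypes, subject=str(subj))
        out[str(subj)] = build_spn(z)
    return out


def mean_spn(spns) -> SPN:
    """Element-wise mean of SPNs sharing one sulcus ordering."""
    spns = list(spns)
    if not spns:
        raise ValueError("need at least one SPN")
    sulci = spns[0].sulci
    for s in spns[1:]:
        if s.sulci != sulci:
            raise ValueError("SPN sulcus orderings differ")
    m = np.mean([s.matrix for s in spns], axis=0)
    np.fill_diagonal(m, 1.0)
    return SPN(sulci, 0.5 * (m + m.T))


def eigen_fold_index(spn: SPN, anchor: str | None = None,
                     reference_axis: np.ndarray | pd.Series | None = None) -> EigenFoldIndex:
    """First principal component of a mean SPN.

    Rows are treated as observations, columns as variables; columns are
    centered but not rescaled (entries already share the correlation scale).
    The sign is fixed so that either `anchor` (a sulcus label; default the
    most-linear sulcus of the shipped annotation) scores positive, or --
    when `reference_axis` is given -- the correlation of the scores with
    that axis is >= 0.
    """
    m = spn.matrix - spn.matrix.mean(axis=0, keepdims=True)
    if np.allclose(m, 0):
        raise ValueError("degenerate SPN: all rows identical")
    # SVD of the centered matrix: row scores on PC1 = u1 * s1
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    scores = u[:, 0] * s[0]
    ev = float(s[0] ** 2 / np.sum(s ** 2))

    if reference_axis is not None:
        ref = np.asarray(
            reference_axis.reindex(list(spn.sulci))
            if isinstance(reference_axis, pd.Series) else reference_axis,
            dtype=float,
        )
        if ref.shape != scores.shape or not np.all(np.isfinite(ref)):
            raise ValueError("reference axis does not align with the SPN sulci")
        if np.corrcoef(scores, ref)[0, 1] < 0:
            scores = -scores
        anchor_id = "reference_axis"
    else:
        anchor_id = anchor if anchor is not None else most_linear_sulcus()
        if anchor_id not in spn.sulci:
            raise ValueError(f"anchor sulcus {anchor_id!r} not in SPN")
        if scores[spn.sulci.index(anchor_id)] < 0:
            scores = -scores
    return EigenFoldIndex(spn.sulci, scores, ev, anchor_id)


def complexity_scores(subject_spn: SPN, efi: EigenFoldIndex,
                      include_diagonal: bool = False) -> pd.DataFrame:
    """Correlate each SPN row with the eigen-fold index.

    By default the self-correlation entry (a constant 1) is excluded from
    each row before correlating, so r_i is computed over the other n-1
    sulci; pass ``include_diagonal=True`` to use all n entries. Returns a
    frame indexed by sulcus with columns ``r`` and ``fisher_z``.
    """
    if subject_spn.sulci != efi.sulci:
        raise ValueError("sulcus ordering mismatch between SPN and eigen-fold index")
    m = subject_spn.matrix
    e = np.asarray(efi.scores, dtype=float)
    n = subject_spn.n
    r = np.empty(n)
    for i in range(n):
        if include_diagonal:
            row, ref = m[i], e
        else:
            keep = np.arange(n) != i
            row, ref = m[i, keep], e[keep]
        if np.ptp(row) == 0:
            raise ValueError(f"constant SPN row for sulcus {subject_spn.sulci[i]!r}")
        r[i] = np.corrcoef(row, ref)[0, 1]
    return pd.DataFrame(
        {"r": r, "fisher_z": fisher_z(r)},
        index=pd.Index(list(subject_spn.sulci), name="sulcus"),
    )


def cross_reference_complexity(subject_spns_by_id: dict[str, SPN],
                               references: dict[str, EigenFoldIndex],
                               include_diagonal: bool = False):
    """Score every subject against several eigen-fold references.

    Returns ``(scores, agreement)`` where `scores` is a long frame
    (subject, reference, sulcus, r, fisher_z) and `agreement` holds the
    per-sulcus correlation of Fisher-Z scores across subjects for each
    reference pair.
    """
    ref_items = list(references.items())
    sulci = ref_items[0][1].sulci
    for _, efi in ref_items:
        if efi.sulci != sulci:
            raise ValueError("references must share one sulcus ordering")
    rows = []
    per_ref: dict[str, pd.DataFrame] = {}
    for ref_name, efi in ref_items:
        zmat = {}
        for subj, spn in subject_spns_by_id.items():
            sc = complexity_scores(spn, efi, include_diagonal=include_diagonal)
            zmat[subj] = sc["fisher_z"]
            block = sc.reset_index()
            block.insert(0, "reference", ref_name)
            block.insert(0, "subject", subj)
            rows.append(block)
        per_ref[ref_name] = pd.DataFrame(zmat)  # sulci x subjects
    scores = pd.concat(rows, ignore_index=True)

    agree_rows = []
    names = [n for n, _ in ref_items]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            za, zb = per_ref[a], per_ref[b]
            for sulcus in sulci:
                agree_rows.append({
                    "reference_a": a, "reference_b": b, "sulcus": sulcus,
                    "agreement": float(np.corrcoef(za.loc[sulcus], zb.loc[sulcus])[0, 1]),
                })
    agreement = pd.DataFrame(agree_rows)
    return scores, agreement


def spn_similarity(a: SPN, b: SPN) -> float:
    """Edge-wise correlation of two SPNs over the strict upper triangle."""
    if a.sulci != b.sulci:
        raise ValueError("sulcus ordering mismatch")
    iu = np.triu_indices(a.n, k=1)
    ea, eb = a.matrix[iu], b.matrix[iu]
    if np.ptp(ea) == 0 or np.ptp(eb) == 0:
        raise ValueError("constant upper triangle; similarity undefined")
    return float(np.corrcoef(ea, eb)[0, 1])


def bipartite_classes(spn: SPN, anchor: str | None = None, seed: int = 0,
                      n_restarts: int = 20) -> pd.Series:
    """Two-group k-means clustering of SPN rows.

    Labels are oriented so the anchor sulcus's class is "linear"; default
    anchor is the most-linear sulcus of the shipped annotation.
    """
    from sklearn.cluster import KMeans

    anchor_id = anchor if anchor is not None else most_linear_sulcus()
    if anchor_id not in spn.sulci:
        raise ValueError(f"anchor sulcus {anchor_id!r} not in SPN")
    m = spn.matrix - spn.matrix.mean(axis=0, keepdims=True)
    if np.allclose(m, 0):
        raise ValueError("degenerate SPN")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed).fit(m)
    anchor_cluster = km.labels_[spn.sulci.index(anchor_id)]
    labels = np.where(km.labels_ == anchor_cluster, "linear", "complex")
    return pd.Series(labels, index=pd.Index(list(spn.sulci), name="sulcus"),
                     name="sulcus_class")
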
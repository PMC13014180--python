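"""Canonical sulcus atlas: 20 bilateral sulci (40 labels) with default annotations.

All matrices and maps in the package are ordered by :data:`CANONICAL_SULCI`.
The default annotation places each sulcus on a linear-to-complex axis in
[-1, 1] (-1 = most linear, +1 = most complex) and assigns a binary
linear/complex class (axis < 0 -> "linear"). User atlases may override via
:func:`sulcnet.io.read_annotation`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Base sulcus names, one per bilateral pair.
SULCUS_NAMES: tuple[str, ...] = (
    "central",
    "precentral",
    "postcentral",
    "superior_frontal",
    "inferior_frontal",
    "intermediate_frontal",
    "orbital",
    "olfactory",
    "anterior_cingulate",
    "posterior_cingulate",
    "superior_temporal",
    "inferior_temporal",
    "occipito_temporal_lateral",
    "collateral",
    "intraparietal",
    "parieto_occipital",
    "occipital",
    "calcarine",
    "insula",
    "subparietal",
)

#: Canonical 40-label ordering: left hemisphere block then right.
CANONICAL_SULCI: tuple[str, ...] = tuple(
    f"{hemi}_{name}" for hemi in ("L", "R") for name in SULCUS_NAMES
)

#: Core phenotypes entering the SPN, in canonical column order.
CORE_PHENOTYPES: tuple[str, ...] = (
    "average_depth",
    "depth_variability",
    "longest_branch",
    "branch_span",
    "fractal_dimension",
)

#: Additional phenotypes carried by a full phenotype table.
EXTRA_PHENOTYPES: tuple[str, ...] = ("surface_area", "thickness", "length")

#: Loadings of the five core phenotypes on the linear pole of the axis:
#: depth phenotypes load positively on "linear", branching/fractal load
#: negatively (i.e. positively on "complex").
LINEAR_POLE_LOADINGS: dict[str, float] = {
    "average_depth": +1.0,
    "depth_variability": +1.0,
    "longest_branch": -1.0,
    "branch_span": -1.0,
    "fractal_dimension": -1.0,
}


def default_annotation() -> pd.DataFrame:
    """Default sulcus annotation table.

    Returns a frame indexed by sulcus with columns ``axis`` (linear-to-complex
    position in [-1, 1], mirrored across hemispheres), ``sulcus_class``
    ("linear"/"complex") and ``hemisphere``.
    """
    n = len(SULCUS_NAMES)
    base = np.linspace(-1.0, 1.0, n)
    axis = np.concatenate([base, base])
    hemi = ["L"] * n + ["R"] * n
    cls = np.where(axis < 0, "linear", "complex")
    return pd.DataFrame(
        {"axis": axis, "sulcus_class": cls, "hemisphere": hemi},
        index=pd.Index(CANONICAL_SULCI, name="sulcus"),
    )


def most_linear_sulcus(annotation: pd.DataFrame | None = None) -> str:
    """Sulcus with the lowest axis position (the default sign anchor)."""
    ann = default_annotation() if annotation is None else annotation
    return str(ann["axis"].idxmin())
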
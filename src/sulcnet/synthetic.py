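"""Seeded generators for every input the analysis chain consumes.

Each generator returns its tables together with a ground-truth record of all
planted quantities, so downstream recovery can be tested. Same seed, same
spec => bit-identical outputs.

Cohort model
------------
Each sulcus occupies a position ``a`` on a latent linear-to-complex axis
(-1 = linear pole, +1 = complex pole). Its expected 5-phenotype profile is a
rotation between two fixed orthogonal directions in phenotype space: at the
complex pole, branching phenotypes (longest branch, branch span, fractal
dimension) are high and depth phenotypes low; the linear pole is the exact
opposite. Cases' axis positions are shifted by the planted per-sulcus effect
map plus ``-contraction * a`` (linear sulci move up the axis, complex sulci
move down). Covariates act as whole-brain expansions/compressions of the
axis (a uniform additive shift would cancel out of the pairwise profile
correlations); phenotype cells add i.i.d. Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._atlas import (
    CANONICAL_SULCI,
    CORE_PHENOTYPES,
    LINEAR_POLE_LOADINGS,
    default_annotation,
)

__all__ = [
    "CohortSpec",
    "GenotypeSpec",
    "ModuleSpec",
    "GeneSetSpec",
    "ExpressionSpec",
    "SimulatedCohort",
    "SimulatedGenotypes",
    "SimulatedExpression",
    "simulate_cohort",
    "simulate_parcellation",
    "simulate_genotypes",
    "simulate_expression",
]

# Complex-pole direction in (AD, DV, LB, BS, FD) space and an orthogonal
# companion spanning the profile rotation plane.
_D1 = -np.array([LINEAR_POLE_LOADINGS[p] for p in CORE_PHENOTYPES]) / np.sqrt(5.0)
_D2 = np.array([1.0, -1.0, 1.0, -1.0, 0.0]) / 2.0

# Radians of profile rotation per unit of axis position.
_AXIS_ANGLE_SCALE = 0.7

_BASELINES = {
    "average_depth": 12.0,
    "depth_variability": 4.0,
    "longest_branch": 40.0,
    "branch_span": 25.0,
    "fractal_dimension": 1.2,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of one case-control cohort."""

    n_cases: int = 100
    n_controls: int = 100
    cohort: str = "SIM"
    sulci: tuple[str, ...] = CANONICAL_SULCI
    latent_axis: np.ndarray | None = None  # default: shipped annotation axis
    effect_map: np.ndarray | None = None  # per-sulcus case shift, default 0
    contraction: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    idio_sd: float = 0.4
    profile_scale: float = 1.0
    age_range: tuple[float, float] = (6.0, 25.0)
    n_sites: int = 2
    seed: int = 0

    def resolved_axis(self) -> np.ndarray:
        if self.latent_axis is not None:
            a = np.asarray(self.latent_axis, dtype=float)
        elif tuple(self.sulci) == CANONICAL_SULCI:
            a = default_annotation()["axis"].to_numpy()
        else:
            a = np.linspace(-1.0, 1.0, len(self.sulci))
        if a.shape != (len(self.sulci),):
            raise ValueError("latent_axis must have one entry per sulcus")
        return a

    def resolved_effects(self) -> np.ndarray:
        if self.effect_map is None:
            return np.zeros(len(self.sulci))
        e = np.asarray(self.effect_map, dtype=float)
        if e.shape != (len(self.sulci),):
            raise ValueError("effect_map must have one entry per sulcus")
        return e

    def validate(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.idio_sd < 0:
            raise ValueError("idio_sd must be non-negative")
        if self.contraction < 0:
            raise ValueError("contraction must be non-negative")
        self.resolved_axis()
        self.resolved_effects()


@dataclass(frozen=True)
class SimulatedCohort:
    table: pd.DataFrame  # long format: subject, cohort, group, sulcus, phenotype, value
    covariates: pd.DataFrame  # one row per subject
    truth: dict


def _profile(axis_position: np.ndarray) -> np.ndarray:
    """Expected 5-phenotype direction for axis positions (complex = +1).

    The angle stays in the near-linear region around pi/2 so that axis
    shifts translate into near-uniform profile changes; it is clipped to
    [0, pi] so extreme shifts saturate monotonically instead of wrapping.
    """
    phi = np.pi / 2.0 - _AXIS_ANGLE_SCALE * axis_position
    return np.outer(np.cos(np.clip(phi, 0.0, np.pi)), _D1) + np.outer(
        np.sin(np.clip(phi, 0.0, np.pi)), _D2)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Simulate a long-format phenotype table for one case-control cohort."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_sub = spec.n_cases + spec.n_controls
    n_sulc = len(spec.sulci)
    axis = spec.resolved_axis()
    effects = spec.resolved_effects()

    subjects = [f"{spec.cohort}_{i:04d}" for i in range(n_sub)]
    group = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)
    is_case = (group == "case").astype(float)

    lo, hi = spec.age_range
    cov = pd.DataFrame({
        "subject": subjects,
        "cohort": spec.cohort,
        "group": group,
        "age": rng.uniform(lo, hi, n_sub),
        "sex": rng.integers(0, 2, n_sub),
        "site": rng.integers(0, max(1, spec.n_sites), n_sub).astype(str),
        "TTV": rng.normal(1.1e6, 1.0e5, n_sub),
        "EN": np.round(rng.normal(-80.0, 30.0, n_sub)).astype(int),
    })

    # Whole-brain axis scaling driven by (centered) covariates.
    kappa = np.zeros(n_sub)
    for name, w in spec.covariate_effects.items():
        if name not in cov.columns:
            raise ValueError(f"unknown covariate {name!r} in covariate_effects")
        col = pd.to_numeric(cov[name]).to_numpy(dtype=float)
        kappa += w * (col - col.mean())

    # subject x sulcus axis positions
    case_shift = effects - spec.contraction * axis
    u = axis[None, :] * (1.0 + kappa[:, None]) + is_case[:, None] * case_shift[None, :]

    prof = _profile(u.reshape(-1)).reshape(n_sub, n_sulc, 5)
    # Stable per-sulcus idiosyncratic direction in the 3-space orthogonal to
    # the axis-rotation plane; keeps SPN rows off the correlation ceiling so
    # coherence responds near-linearly to axis shifts.
    q3 = np.linalg.qr(np.column_stack([_D1, _D2, rng.standard_normal((5, 3))]))[0][:, 2:]
    idio = rng.standard_normal((n_sulc, 3))
    idio /= np.linalg.norm(idio, axis=1, keepdims=True)
    prof = prof + spec.idio_sd * (idio @ q3.T)[None, :, :]
    base = np.array([_BASELINES[p] for p in CORE_PHENOTYPES])
    x = base[None, None, :] + spec.profile_scale * prof
    x = x + rng.normal(0.0, spec.noise_sd, size=x.shape)

    length = rng.lognormal(mean=3.4, sigma=0.25, size=(n_sub, n_sulc))
    thickness = rng.normal(2.5, 0.2, size=(n_sub, n_sulc))

    frames = []
    for k, phen in enumerate(CORE_PHENOTYPES):
        frames.append(pd.DataFrame({
            "subject": np.repeat(subjects, n_sulc),
            "sulcus": np.tile(spec.sulci, n_sub),
            "phenotype": phen,
            "value": x[:, :, k].reshape(-1),
        }))
    for phen, mat in (("length", length), ("thickness", thickness)):
        frames.append(pd.DataFrame({
            "subject": np.repeat(subjects, n_sulc),
            "sulcus": np.tile(spec.sulci, n_sub),
            "phenotype": phen,
            "value": mat.reshape(-1),
        }))
    table = pd.concat(frames, ignore_index=True)
    table = table.merge(cov, on="subject", how="left")
    table = table[["subject", "cohort", "group", "sulcus", "phenotype", "value",
                   "age", "sex", "site", "TTV", "EN"]]

    truth = {
        "latent_axis": pd.Series(axis, index=list(spec.sulci), name="axis"),
        "effect_map": pd.Series(effects, index=list(spec.sulci), name="effect"),
        "contraction": spec.contraction,
        "covariate_effects": dict(spec.covariate_effects),
        "sulcus_class": pd.Series(np.where(axis < 0, "linear", "complex"),
                                  index=list(spec.sulci), name="sulcus_class"),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return SimulatedCohort(table=table, covariates=cov, truth=truth)


def simulate_parcellation(n_sulci: int, seed: int = 0, unilateral: bool = False,
                          sulci=None) -> pd.DataFrame:
    """Unit-sphere centroids for a spin-test parcellation.

    Left-hemisphere centroids are uniform on the sphere; right-hemisphere
    centroids are their x-mirrored twins. Returns columns sulcus,
    hemisphere, x, y, z.
    """
    if n_sulci < 3:
        raise ValueError("need at least 3 sulci")
    if not unilateral and n_sulci % 2:
        raise ValueError("n_sulci must be even for a bilateral parcellation")
    rng = np.random.default_rng(seed)
    n_left = n_sulci if unilateral else n_sulci // 2
    pts = rng.standard_normal((n_left, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    if unilateral:
        coords = pts
        hemi = ["L"] * n_sulci
    else:
        coords = np.vstack([pts, pts * np.array([-1.0, 1.0, 1.0])])
        hemi = ["L"] * n_left + ["R"] * n_left
    if sulci is None:
        sulci = (CANONICAL_SULCI if n_sulci == len(CANONICAL_SULCI) and not unilateral
                 else [f"{h}_s{i % n_left:02d}" for i, h in enumerate(hemi)])
    return pd.DataFrame({
        "sulcus": list(sulci),
        "hemisphere": hemi,
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
    })


@dataclass(frozen=True)
class GenotypeSpec:
    n_subjects: int = 1000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_size: int = 10
    within_block_r: float = 0.8
    causal: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError("within_block_r must lie in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        for idx, _ in self.causal:
            if not (0 <= idx < self.n_snps):
                raise ValueError(f"causal index {idx} out of range")


@dataclass(frozen=True)
class SimulatedGenotypes:
    dosages: np.ndarray  # subjects x snps, values in {0,1,2}
    variants: pd.DataFrame  # id, chrom, pos, ref, alt, maf, block
    subjects: list[str]
    phenotype_contribution: np.ndarray  # per-subject sum of causal effects
    truth: dict


def simulate_genotypes(spec: GenotypeSpec) -> SimulatedGenotypes:
    """LD-blocked biallelic dosages via a thresholded latent Gaussian.

    Haplotype alleles within a block share a latent factor with loading
    sqrt(within_block_r), giving exchangeable within-block LD; blocks are
    mutually independent.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_subjects, spec.n_snps
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], m)
    thresh = _norm_ppf(mafs)
    blocks = np.arange(m) // spec.block_size
    n_blocks = int(blocks.max()) + 1
    r = spec.within_block_r

    dosage = np.zeros((n, m), dtype=np.int16)
    for hap in range(2):
        shared = rng.standard_normal((n, n_blocks))
        z = np.sqrt(r) * shared[:, blocks] + np.sqrt(1.0 - r) * rng.standard_normal((n, m))
        dosage += (z < thresh[None, :]).astype(np.int16)

    variants = pd.DataFrame({
        "id": [f"snp{i:05d}" for i in range(m)],
        "chrom": "1",
        "pos": 10_000 * (np.arange(m) + 1),
        "ref": "A",
        "alt": "G",
        "maf": mafs,
        "block": blocks,
    })
    subjects = [f"S{i:05d}" for i in range(n)]
    contrib = np.zeros(n)
    for idx, beta in spec.causal:
        d = dosage[:, idx].astype(float)
        contrib += beta * (d - d.mean())
    truth = {"causal": list(spec.causal), "maf": mafs, "block": blocks,
             "seed": spec.seed}
    return SimulatedGenotypes(dosage, variants, subjects, contrib, truth)


def _norm_ppf(q):
    from scipy.stats import norm

    return norm.ppf(q)


DEFAULT_LAYERS = ("cortical_plate", "subplate", "intermediate_zone",
                  "subventricular_zone", "ventricular_zone")
DEFAULT_TIMEPOINTS = ("pcw16", "pcw21")


@dataclass(frozen=True)
class ModuleSpec:
    n_genes: int
    peak_layer: int  # index into layers
    peak_timepoint: int  # index into timepoints
    amplitude: float = 3.0


@dataclass(frozen=True)
class GeneSetSpec:
    name: str
    module: int  # 0-based index into ExpressionSpec.modules
    overlap: float  # fraction of the set drawn from that module's genes
    size: int | None = None  # default: the module's gene count

    def validate(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ExpressionSpec:
    n_genes: int = 60
    regions: tuple[str, ...] = tuple(f"region{i:02d}" for i in range(20))
    layers: tuple[str, ...] = DEFAULT_LAYERS
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    modules: tuple[ModuleSpec, ...] = ()
    noise_sd: float = 1.0
    gene_sets: tuple[GeneSetSpec, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if sum(m.n_genes for m in self.modules) > self.n_genes:
            raise ValueError("module gene counts exceed n_genes")
        for m in self.modules:
            if not (0 <= m.peak_layer < len(self.layers)):
                raise ValueError("peak_layer out of range")
            if not (0 <= m.peak_timepoint < len(self.timepoints)):
                raise ValueError("peak_timepoint out of range")
        for gs in self.gene_sets:
            gs.validate()
            if not (0 <= gs.module < max(1, len(self.modules))):
                raise ValueError(f"gene set {gs.name!r} references unknown module")


@dataclass(frozen=True)
class SimulatedExpression:
    cube: pd.DataFrame  # long: gene, region, layer, timepoint, value
    module_labels: pd.Series  # per-gene truth ("module1".../"background")
    gene_sets: dict[str, list[str]]
    truth: dict


def _module_pattern(spec: ExpressionSpec, mod: ModuleSpec) -> np.ndarray:
    """Deterministic (region, layer, timepoint) expression surface."""
    n_r, n_l, n_t = len(spec.regions), len(spec.layers), len(spec.timepoints)
    li = np.arange(n_l)
    out = np.zeros((n_r, n_l, n_t))
    for t in range(n_t):
        # bump over layers; off-peak timepoints express a weaker, shifted bump
        if t == mod.peak_timepoint:
            center, gain = mod.peak_layer, 1.0
        else:
            center, gain = min(mod.peak_layer + 1, n_l - 1), 0.3
        layer_kernel = np.exp(-0.5 * (li - center) ** 2)
        region_mod = 1.0 + 0.3 * np.cos(
            2.0 * np.pi * np.arange(n_r) / n_r + mod.peak_layer
        )
        out[:, :, t] = gain * mod.amplitude * np.outer(region_mod, layer_kernel)
    return out


def simulate_expression(spec: ExpressionSpec) -> SimulatedExpression:
    """Expression cube with planted (layer, timepoint) modules and GMT sets."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_r, n_l, n_t = len(spec.regions), len(spec.layers), len(spec.timepoints)
    genes = [f"gene{i:04d}" for i in range(spec.n_genes)]

    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_r, n_l, n_t))
    labels = np.array(["background"] * spec.n_genes, dtype=object)
    g = 0
    module_members: list[list[str]] = []
    for mi, mod in enumerate(spec.modules):
        pattern = _module_pattern(spec, mod)
        members = []
        for _ in range(mod.n_genes):
            values[g] += pattern
            labels[g] = f"module{mi + 1}"
            members.append(genes[g])
            g += 1
        module_members.append(members)

    idx = pd.MultiIndex.from_product(
        [genes, spec.regions, spec.layers, spec.timepoints],
        names=["gene", "region", "layer", "timepoint"],
    )
    cube = pd.DataFrame({"value": values.reshape(-1)}, index=idx).reset_index()

    gene_sets: dict[str, list[str]] = {}
    background = [genes[i] for i in range(spec.n_genes)
                  if labels[i] == "background"]
    for gs in spec.gene_sets:
        members = module_members[gs.module] if spec.modules else []
        size = gs.size if gs.size is not None else max(1, len(members))
        n_in = int(round(gs.overlap * size))
        n_in = min(n_in, len(members))
        chosen = list(rng.choice(members, size=n_in, replace=False)) if n_in else []
        pool = [x for x in genes if x not in chosen]
        extra = list(rng.choice(pool, size=size - n_in, replace=False))
        gene_sets[gs.name] = sorted(chosen) + sorted(extra)

    truth = {"module_members": module_members, "seed": spec.seed}
    return SimulatedExpression(
        cube=cube,
        module_labels=pd.Series(labels, index=pd.Index(genes, name="gene"),
                                name="module"),
        gene_sets=gene_sets,
        truth=truth,
    )
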
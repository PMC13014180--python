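"""Readers and writers for the package's plain-text formats.

Everything is TSV (tables, square matrices, maps), GMT (gene sets), BED or
a native 1-based TSV (gene intervals) and JSON (configs, ground truth).
Writers prepend a comment header carrying the run id and config hash so
every output is traceable; readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spn import SPN

__all__ = [
    "read_phenotype_table",
    "write_phenotype_table",
    "derive_surface_area",
    "read_spn",
    "write_spn",
    "read_map",
    "write_map",
    "read_parcellation",
    "write_parcellation",
    "read_gmt",
    "write_gmt",
    "read_gene_intervals",
    "read_genotypes",
    "write_genotypes",
    "write_table",
    "read_table",
    "config_hash",
]

PHENOTYPE_COLUMNS = ["subject", "cohort", "group", "sulcus", "phenotype", "value",
                     "age", "sex", "site", "TTV", "EN"]


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header(run_id: str | None, cfg_hash: str | None) -> str:
    if run_id is None and cfg_hash is None:
        return ""
    return f"# run_id={run_id or 'adhoc'} config_hash={cfg_hash or 'none'}\n"


def write_table(df: pd.DataFrame, path, index: bool = False,
                run_id: str | None = None, cfg_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(run_id, cfg_hash))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_phenotype_table(table: pd.DataFrame, path, **meta) -> None:
    write_table(table[PHENOTYPE_COLUMNS], path, **meta)


def read_phenotype_table(path) -> pd.DataFrame:
    """Typed, validated long-format phenotype table.

    Rejects schema violations and duplicate (subject, sulcus, phenotype)
    rows with row numbers.
    """
    df = read_table(path, dtype={"subject": str, "cohort": str, "group": str,
                                 "sulcus": str, "phenotype": str, "site": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    dup = df.duplicated(subset=["subject", "sulcus", "phenotype"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]
        raise ValueError(f"duplicate (subject, sulcus, phenotype) rows at lines {rows}")
    bad_group = ~df["group"].isin(["case", "control"])
    if bad_group.any():
        rows = (df.index[bad_group] + 2).tolist()[:10]
        raise ValueError(f"invalid group labels at lines {rows}")
    return df[PHENOTYPE_COLUMNS]


def validate_complete(table: pd.DataFrame, sulci, phenotypes) -> None:
    """Every subject must carry every (sulcus, phenotype) pair."""
    expected = len(sulci) * len(phenotypes)
    counts = (table[table["phenotype"].isin(phenotypes)]
              .groupby("subject").size())
    bad = counts[counts != expected]
    if not bad.empty:
        raise ValueError(f"incomplete sulcus/phenotype grid for subjects "
                         f"{list(bad.index)[:5]}")


def derive_surface_area(table: pd.DataFrame) -> pd.DataFrame:
    """Append surface_area = average_depth * length rows (units mm^2)."""
    wide = table.pivot_table(index=["subject", "sulcus"], columns="phenotype",
                             values="value", aggfunc="first")
    for col in ("average_depth", "length"):
        if col not in wide.columns:
            raise ValueError(f"missing {col!r} column for surface area")
        if (wide[col] < 0).any():
            raise ValueError(f"negative {col!r} values")
    area = (wide["average_depth"] * wide["length"]).rename("value").reset_index()
    area["phenotype"] = "surface_area"
    meta_cols = [c for c in table.columns
                 if c not in ("sulcus", "phenotype", "value")]
    meta = table[meta_cols].drop_duplicates("subject")
    area = area.merge(meta, on="subject", how="left")
    out = pd.concat([table, area[table.columns]], ignore_index=True)
    return out


def write_spn(spn: SPN, path, **meta) -> None:
    write_table(spn.to_frame(), path, index=True, **meta)


def read_spn(path) -> SPN:
    df = read_table(path, index_col=0)
    return SPN(tuple(str(s) for s in df.index), df.to_numpy(dtype=float))


def write_map(series: pd.Series, path, **meta) -> None:
    df = series.rename("value").rename_axis("sulcus").reset_index()
    write_table(df, path, **meta)


def read_map(path) -> pd.Series:
    df = read_table(path)
    return pd.Series(df["value"].to_numpy(dtype=float),
                     index=pd.Index(df["sulcus"].astype(str), name="sulcus"),
                     name="value")


def write_parcellation(parc: pd.DataFrame, path, **meta) -> None:
    write_table(parc[["sulcus", "hemisphere", "x", "y", "z"]], path, **meta)


def read_parcellation(path) -> pd.DataFrame:
    df = read_table(path, dtype={"sulcus": str, "hemisphere": str})
    norms = np.linalg.norm(df[["x", "y", "z"]].to_numpy(dtype=float), axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("parcellation centroids must have unit norm")
    if not set(df["hemisphere"]) <= {"L", "R"}:
        raise ValueError("hemisphere must be L or R")
    return df


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = parts[2:]
    return out


def read_gene_intervals(path, fmt: str = "auto") -> pd.DataFrame:
    """Gene intervals as 1-based inclusive (gene, chrom, start, end).

    BED input (0-based half-open; columns chrom, start, end, name) is
    converted on read. The native TSV format has a header with columns
    gene, chrom, start, end already 1-based inclusive.
    """
    if fmt == "auto":
        fmt = "bed" if str(path).endswith(".bed") else "tsv"
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "gene"],
                         usecols=[0, 1, 2, 3])
        df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
        df["end"] = df["end"].astype(int)
    else:
        df = read_table(path, dtype={"gene": str, "chrom": str})
    df["chrom"] = df["chrom"].astype(str)
    if (df["end"] < df["start"]).any():
        raise ValueError("malformed gene intervals")
    return df[["gene", "chrom", "start", "end"]]


def write_genotypes(dosages: np.ndarray, variants: pd.DataFrame, subjects,
                    prefix, **meta) -> None:
    prefix = Path(prefix)
    dmat = pd.DataFrame(np.asarray(dosages), index=pd.Index(subjects, name="subject"),
                        columns=variants["id"])
    write_table(dmat, prefix.with_suffix(".dosage.tsv"), index=True, **meta)
    write_table(variants, prefix.with_suffix(".variants.tsv"), **meta)


def read_vcf(path):
    """Plain-text VCF to dosages (GT field, biallelic records only).

    Returns ``(dosages, variants, subjects)`` like :func:`read_genotypes`.
    Multi-allelic records are rejected; missing genotypes become NaN.
    """
    subjects: list[str] = []
    rows = []
    dosage_rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                subjects = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise ValueError(f"multi-allelic record at {chrom}:{pos}")
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            doses = []
            for sample in fields[9:]:
                gt = sample.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    doses.append(np.nan)
                else:
                    doses.append(sum(int(a) for a in gt.split("/")))
            rows.append({"id": vid, "chrom": chrom, "pos": int(pos),
                         "ref": ref, "alt": alt})
            dosage_rows.append(doses)
    if not subjects:
        raise ValueError("no #CHROM header line found")
    variants = pd.DataFrame(rows)
    dosages = np.asarray(dosage_rows, dtype=float).T  # subjects x variants
    return dosages, variants, subjects


def read_genotypes(prefix):
    prefix = Path(prefix)
    dmat = read_table(prefix.with_suffix(".dosage.tsv"), index_col=0)
    variants = read_table(prefix.with_suffix(".variants.tsv"),
                          dtype={"id": str, "chrom": str})
    return dmat.to_numpy(dtype=float), variants, list(dmat.index.astype(str))
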
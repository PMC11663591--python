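"""Readers and writers for the pipeline's plain-text formats.

Coordinate conventions, always labelled in file headers:

* native TSVs use 1-based inclusive positions (matching SNP reporting);
* BED exports are 0-based half-open.

Genotype matrices are TSVs with ``chrom`` and ``pos`` columns followed by
one column per individual, cells in {A, H, B, -}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import RegionAnnotation
from .hotspots import HotspotDef

__all__ = [
    "read_genotype_matrix",
    "write_genotype_matrix",
    "write_crossover_calls",
    "read_crossover_calls",
    "read_marker_map",
    "read_region_annotation_bed",
    "read_hotspots_bed",
    "read_seed_counts_csv",
    "write_seed_counts_csv",
    "read_recombinant_vectors",
    "write_recombinant_vectors",
    "write_sim_truth",
    "read_sim_truth",
    "PipelineConfig",
    "load_config",
]

VALID_CALLS = {"A", "H", "B", "-"}


class ParseError(ValueError):
    pass


def _write_with_header(df: pd.DataFrame, path, header_lines: list[str]) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- genotype matrices -------------------------------------------------------


def read_genotype_matrix(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genotype matrix TSV; returns ``(markers, genotypes)``.

    ``markers`` is the ``chrom, pos`` scaffold; ``genotypes`` is the full
    matrix including the scaffold columns.  Duplicate (chrom, pos) rows are
    an error; unsorted rows are sorted with a warning; any cell outside
    {A, H, B, -} raises a :class:`ParseError` naming its coordinates.
    """
    df = _read_table(path, dtype={"chrom": str})
    if df.empty or "chrom" not in df.columns or "pos" not in df.columns:
        raise ParseError(f"{path}: no markers (need chrom, pos and individual columns)")
    if df.duplicated(subset=["chrom", "pos"]).any():
        dup = df.loc[df.duplicated(subset=["chrom", "pos"]), ["chrom", "pos"]].iloc[0]
        raise ParseError(f"{path}: duplicate marker {dup['chrom']}:{dup['pos']}")
    ind_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    if not ind_cols:
        raise ParseError(f"{path}: no individual columns")
    for col in ind_cols:
        bad = ~df[col].isin(VALID_CALLS)
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise ParseError(
                f"{path}: invalid call '{row[col]}' at {row['chrom']}:{row['pos']} "
                f"(individual {col})"
            )
    sorted_df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if not sorted_df[["chrom", "pos"]].equals(df[["chrom", "pos"]].reset_index(drop=True)):
        warnings.warn(f"{path}: markers were not sorted; sorting", stacklevel=2)
    return sorted_df[["chrom", "pos"]].copy(), sorted_df


def write_genotype_matrix(genotypes: pd.DataFrame, path, seed=None) -> None:
    header = ["genotype matrix; coordinates 1-based; calls A/H/B/-"]
    if seed is not None:
        header.append(f"seed={seed}")
    _write_with_header(genotypes, path, header)


# -- crossover calls ---------------------------------------------------------


def write_crossover_calls(calls: pd.DataFrame, path, dialect: str = "native",
                          seed=None) -> None:
    """Write calls as TSV in the ``native`` (1-based inclusive flanking
    markers) or ``bed`` (0-based half-open) dialect."""
    if dialect not in ("native", "bed"):
        raise ValueError("dialect must be 'native' or 'bed'")
    header = [f"crossover calls; dialect={dialect}"]
    if seed is not None:
        header.append(f"seed={seed}")
    if dialect == "native":
        header[0] += "; left_pos/right_pos are 1-based inclusive marker positions"
        out = calls[["individual", "chrom", "left_pos", "right_pos",
                     "midpoint", "multiplicity"]]
    else:
        header[0] += "; start/end are 0-based half-open"
        out = pd.DataFrame(
            {
                "chrom": calls["chrom"],
                "start": calls["left_pos"] - 1,
                "end": calls["right_pos"],
                "individual": calls["individual"],
                "midpoint": calls["midpoint"],
                "multiplicity": calls["multiplicity"],
            }
        )
    _write_with_header(out, path, header)


def read_crossover_calls(path) -> pd.DataFrame:
    """Read native-dialect calls back into the in-memory layout."""
    df = _read_table(path, dtype={"chrom": str, "individual": str})
    required = {"individual", "chrom", "left_pos", "right_pos", "midpoint", "multiplicity"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: not a native call table (missing {sorted(missing)})")
    return df


# -- marker maps, annotations, hotspots --------------------------------------


def read_marker_map(path) -> pd.DataFrame:
    df = _read_table(path, dtype={"chrom": str})
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise ParseError(f"{path}: marker map needs chrom and pos columns")
    if df.duplicated(subset=["chrom", "pos"]).any():
        raise ParseError(f"{path}: duplicate markers")
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def read_region_annotation_bed(path) -> RegionAnnotation:
    """BED (0-based half-open) with name in {arm, pericentromere, centromere}."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "name"], dtype={"chrom": str})
    regions: dict[str, dict[str, list[tuple[int, int]]]] = {}
    lengths: dict[str, int] = {}
    for _, row in df.iterrows():
        label = row["name"]
        if label not in ("arm", "pericentromere", "centromere"):
            raise ParseError(f"{path}: unknown region label '{label}'")
        chrom = row["chrom"]
        regions.setdefault(chrom, {"arm": [], "pericentromere": [], "centromere": []})
        # BED half-open -> 1-based inclusive
        regions[chrom][label].append((int(row["start"]) + 1, int(row["end"])))
        lengths[chrom] = max(lengths.get(chrom, 0), int(row["end"]))
    return RegionAnnotation(regions=regions, lengths=lengths)


def read_hotspots_bed(path) -> list[HotspotDef]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "name"], dtype={"chrom": str})
    return [
        HotspotDef(name=row["name"], start=int(row["start"]) + 1, end=int(row["end"]))
        for _, row in df.iterrows()
    ]


# -- seed counts and recombinant vectors --------------------------------------


def read_seed_counts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"plant_id", "genotype", "n_green_only", "n_red_only", "n_both", "n_none"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: seed count table missing {sorted(missing)}")
    return df


def write_seed_counts_csv(df: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write("# seed fluorescence class counts per plant\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_recombinant_vectors(path) -> pd.DataFrame:
    df = _read_table(path, dtype=str)
    if "id" not in df.columns or len(df.columns) < 3:
        raise ParseError(f"{path}: recombinant vectors need id plus >= 2 SNP columns")
    return df


def write_recombinant_vectors(vectors: pd.DataFrame, path, seed=None) -> None:
    header = ["recombinant genotype vectors; columns are 1-based SNP positions"]
    if seed is not None:
        header.append(f"seed={seed}")
    _write_with_header(vectors, path, header)


def write_sim_truth(truth: pd.DataFrame, path, seed=None) -> None:
    header = ["simulated crossover ground truth; pos_bp 1-based"]
    if seed is not None:
        header.append(f"seed={seed}")
    _write_with_header(truth, path, header)


def read_sim_truth(path) -> pd.DataFrame:
    return _read_table(path, dtype={"chrom": str, "individual": str})


# -- pipeline configuration ---------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``load_config``)."""

    seed: int
    n_individuals: int
    out_dir: Path
    marker_spacing_bp: int = 50_000
    genome: dict = field(default_factory=dict)
    meiosis: dict = field(default_factory=dict)
    observation: dict = field(default_factory=dict)
    caller: dict = field(default_factory=dict)
    window_bp: int = 300_000
    n_bins: int = 50
    annotation_bed: Path | None = None
    hotspots_bed: Path | None = None
    seed_counts_csv: Path | None = None


def load_config(path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("seed", "n_individuals", "out_dir"):
        if key not in raw:
            raise ParseError(f"{path}: missing required key '{key}'")
    cfg = PipelineConfig(**raw)
    cfg.out_dir = Path(cfg.out_dir)
    for name in ("annotation_bed", "hotspots_bed", "seed_counts_csv"):
        value = getattr(cfg, name)
        if value is not None:
            p = Path(value)
            if not p.is_absolute():
                p = path.parent / p
            if not p.exists():
                raise ParseError(f"{path}: referenced file does not exist: {p}")
            setattr(cfg, name, p)
    return cfg
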
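"""Tab-separated and VCF readers/writers plus the pipeline configuration.

All tabular artifacts are plain TSV so that runs are diffable and portable:
base counts (cell, pos, A, C, G, T), cell metadata (cell, donor, age_years,
species), pathology annotation (pos, ref, alt, class), reference
(pos, ref; FASTA also accepted), variant tables, and cSFS histograms.  The
VCF writer emits minimal VCF 4.2 with per-cell AF and DP sample fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .variant_calling import BASES

__all__ = [
    "MalformedInputError",
    "PipelineConfig",
    "read_base_counts",
    "write_base_counts",
    "read_metadata",
    "write_metadata",
    "read_annotation",
    "write_annotation",
    "read_reference",
    "write_reference",
    "read_variant_table",
    "write_variant_table",
    "write_csfs",
]


class MalformedInputError(ValueError):
    """A tabular input failed validation; the message names the lines."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]  # 1-based + header
            raise MalformedInputError(
                f"{path}: non-numeric values in column {c!r} at line(s) {lines}"
            )
        df[c] = coerced
    return df


def read_base_counts(path, metadata_path=None) -> pd.DataFrame:
    """Read a base-count TSV; merge donor ids from metadata when given."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["cell", "pos", *BASES], path)
    df = _numeric(df, ["pos", *BASES], path)
    df["pos"] = df["pos"].astype(int)
    df[BASES] = df[BASES].astype(int)
    if (df[BASES].to_numpy() < 0).any():
        raise MalformedInputError(f"{path}: negative base counts")
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        df = df.merge(meta[["cell", "donor"]], on="cell", how="left")
        if df["donor"].isna().any():
            orphan = df.loc[df["donor"].isna(), "cell"].unique()[:5]
            raise MalformedInputError(
                f"{path}: cells missing from metadata: {orphan.tolist()}"
            )
    cols = ["cell"] + (["donor"] if "donor" in df.columns else []) + ["pos", *BASES]
    return df[cols]


def write_base_counts(counts: pd.DataFrame, path) -> None:
    counts[["cell", "pos", *BASES]].to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    _require_columns(meta, ["cell", "donor", "age_years", "species"], path)
    return _numeric(meta, ["age_years"], path)


def write_metadata(cells: pd.DataFrame, path) -> None:
    cells[["cell", "donor", "age_years", "species"]].to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    _require_columns(ann, ["pos", "ref", "alt", "class"], path)
    return _numeric(ann, ["pos"], path).astype({"pos": int})


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[["pos", "ref", "alt", "class"]].to_csv(path, sep="\t", index=False)


def read_reference(path) -> pd.Series:
    """Read a reference as two-column TSV (pos, ref) or as FASTA."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        from Bio import SeqIO

        record = next(SeqIO.parse(str(path), "fasta"))
        seq = str(record.seq).upper()
        return pd.Series(list(seq), index=np.arange(1, len(seq) + 1))
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["pos", "ref"], path)
    df = _numeric(df, ["pos"], path)
    return pd.Series(df["ref"].to_numpy(), index=df["pos"].astype(int).to_numpy())


def write_reference(reference: pd.Series, path) -> None:
    pd.DataFrame({"pos": reference.index, "ref": reference.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_variant_table(path) -> pd.DataFrame:
    vt = pd.read_csv(path, sep="\t")
    _require_columns(
        vt, ["cell", "donor", "site", "ref", "alt", "heteroplasmy", "depth"], path
    )
    return _numeric(vt, ["site", "heteroplasmy", "depth"], path).astype(
        {"site": int, "depth": int}
    )


def write_variant_table(vt: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write a variant table as TSV (lossless) or minimal VCF 4.2."""
    if format == "tsv":
        vt.to_csv(path, sep="\t", index=False)
    elif format == "vcf":
        _write_vcf(vt, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_vcf(vt: pd.DataFrame, path, contig: str = "chrM") -> None:
    cells = sorted(vt["cell"].unique())
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig}>",
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction (heteroplasmy)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cells),
    ]
    by_cell = {
        (r.site, r.ref, r.alt): {}
        for r in vt.itertuples()
    }
    for r in vt.itertuples():
        by_cell[(r.site, r.ref, r.alt)][r.cell] = (r.heteroplasmy, r.depth)
    for (site, ref, alt) in sorted(by_cell):
        entries = by_cell[(site, ref, alt)]
        samples = [
            f"{entries[c][0]:.6g}:{entries[c][1]}" if c in entries else ".:."
            for c in cells
        ]
        lines.append(
            f"{contig}\t{site}\t.\t{ref}\t{alt}\t.\tPASS\t.\tAF:DP\t"
            + "\t".join(samples)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_csfs(csfs, path_hist, path_raw=None) -> None:
    """Write a cSFS histogram (bin_left, bin_right, count, density) and raw list."""
    csfs.to_frame().to_csv(path_hist, sep="\t", index=False)
    if path_raw is not None:
        pd.DataFrame({"heteroplasmy": csfs.heteroplasmies}).to_csv(
            path_raw, sep="\t", index=False
        )


@dataclass
class PipelineConfig:
    """Single source of truth for an end-to-end run (YAML-serializable)."""

    counts: str = ""
    metadata: str = ""
    annotation: str = ""
    reference: str = ""
    out_dir: str = "mitocrypt_out"
    min_depth: int = 200
    min_positions: int = 200
    sigma_mult: float = 3.0
    cryptic_floor: float = 0.05
    report_floor: float = 0.10
    common_donor_count: int = 3
    min_cells_per_site: int = 10
    homoplasmy_cut: float = 0.95
    bulk_cut: float = 0.005
    bins: int = 20
    N: int = 1000
    reference_N: int = 100
    w_max: float = 3.0
    theta_bounds: tuple = (1e-7, 1e-2)
    run_fit: bool = False
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        checks = {
            "min_depth": self.min_depth >= 0,
            "min_positions": self.min_positions >= 0,
            "sigma_mult": self.sigma_mult > 0,
            "cryptic_floor": 0 <= self.cryptic_floor < 1,
            "report_floor": 0 <= self.report_floor < 1,
            "common_donor_count": self.common_donor_count >= 1,
            "min_cells_per_site": self.min_cells_per_site >= 1,
            "homoplasmy_cut": 0 < self.homoplasmy_cut <= 1,
            "bulk_cut": 0 < self.bulk_cut < 1,
            "N": self.N >= 2,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"config value(s) out of domain: {bad}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)  # nested sections are flattened
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise MalformedInputError(f"{path}: unknown config key(s) {sorted(unknown)}")
        flat.update({k: v for k, v in overrides.items() if v is not None})
        if "theta_bounds" in flat:
            flat["theta_bounds"] = tuple(float(x) for x in flat["theta_bounds"])
        return cls(**flat)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
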
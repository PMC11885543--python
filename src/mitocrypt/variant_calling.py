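"""Heteroplasmy calling and cryptic/shared/common classification.

The heteroplasmy of base i at a position is the read fraction
h_i = N_i / (N_A + N_C + N_G + N_T).  A position in a cell qualifies when
strictly more than ``min_depth`` reads cover it; a cell is retained when it
has at least ``min_positions`` qualifying positions and its qualifying-count
lies within ``sigma_mult`` standard deviations of the cohort mean in log10
space.  A mutation is *cryptic* when its (site, alt) pair is seen above the
cryptic floor in exactly one cell of the donor; mutations present in more
than ``common_donor_count`` donors are *common* (likely inherited/RNA
variants) and everything else above the floor is *shared*.

Base-quality (>= 30) and unique-alignment (NUMT) filtering are applied when
ingesting alignments with :func:`base_counts_from_alignment`; tabular base
counts are assumed to have had them applied upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = ["A", "C", "G", "T"]

__all__ = [
    "QCMask",
    "EmptyCohortError",
    "qc_filter",
    "call_variants",
    "classify_variants",
    "annotate_variants",
    "base_counts_from_alignment",
]


class EmptyCohortError(RuntimeError):
    """Raised when quality control excludes every cell of a cohort."""


@dataclass
class QCMask:
    """Quality-control decisions derived from a base-count matrix."""

    qualified: pd.Series  # bool, indexed by (cell, pos)
    retained_cells: pd.Series  # bool, indexed by cell
    qualified_per_cell: pd.Series  # int, indexed by cell
    site_cell_counts: pd.Series  # int, indexed by (donor, pos); retained cells only
    min_depth: int
    min_positions: int
    sigma_mult: float

    @property
    def n_retained(self) -> int:
        return int(self.retained_cells.sum())


def _depths(counts: pd.DataFrame) -> pd.Series:
    return counts[BASES].sum(axis=1)


def qc_filter(
    counts: pd.DataFrame,
    min_depth: int = 200,
    min_positions: int = 200,
    sigma_mult: float = 3.0,
) -> QCMask:
    """Depth and cell-level quality control on a base-count matrix.

    ``counts`` is long-form with columns cell, donor, pos, A, C, G, T.
    A (cell, pos) qualifies iff its total depth strictly exceeds
    ``min_depth``.  Cells need >= ``min_positions`` qualifying positions and
    must not be log-normal outliers (mean +/- ``sigma_mult`` SD of log10
    qualifying-count, computed over the cells passing the absolute filter;
    zero cohort variance retains everybody).
    """
    if counts.empty:
        raise ValueError("empty base-count matrix")
    depth = _depths(counts)
    qualified = pd.Series(
        (depth > min_depth).to_numpy(),
        index=pd.MultiIndex.from_frame(counts[["cell", "pos"]]),
        name="qualified",
    )
    q_per_cell = (
        pd.Series(qualified.to_numpy(), index=counts["cell"].to_numpy())
        .groupby(level=0)
        .sum()
        .astype(int)
    )
    passes_abs = q_per_cell >= min_positions
    retained = passes_abs.copy()
    pool = q_per_cell[passes_abs]
    if len(pool) > 0:
        logq = np.log10(pool.to_numpy(dtype=float))
        mu, sd = logq.mean(), logq.std(ddof=0)
        if sd > 0:
            ok = np.abs(logq - mu) <= sigma_mult * sd
            retained.loc[pool.index] = ok
    if not retained.any():
        raise EmptyCohortError(
            "quality control excluded all cells "
            f"(min_depth={min_depth}, min_positions={min_positions})"
        )
    cell_ok = counts["cell"].map(retained).to_numpy()
    live = counts[cell_ok & qualified.to_numpy()]
    site_cell_counts = live.groupby(["donor", "pos"]).size()
    return QCMask(
        qualified=qualified,
        retained_cells=retained,
        qualified_per_cell=q_per_cell,
        site_cell_counts=site_cell_counts,
        min_depth=min_depth,
        min_positions=min_positions,
        sigma_mult=sigma_mult,
    )


def _reference_series(reference, positions: np.ndarray) -> pd.Series:
    """Normalize a reference (dict / Series / str sequence) to pos -> base."""
    if isinstance(reference, str):
        ref = pd.Series(list(reference), index=np.arange(1, len(reference) + 1))
    elif isinstance(reference, dict):
        ref = pd.Series(reference)
    else:
        ref = pd.Series(reference)
    missing = np.setdiff1d(positions, ref.index.to_numpy())
    if missing.size:
        raise KeyError(
            f"reference base missing for position(s) {missing[:5].tolist()}"
        )
    return ref.astype(str).str.upper()


def call_variants(
    counts: pd.DataFrame,
    mask: QCMask,
    reference,
) -> pd.DataFrame:
    """Emit every non-reference base with reads at each qualified position.

    One row per (cell, site, alt base); several alternate bases at one site
    give several rows (reads are not deduplicated and the read fractions at a
    site sum to 1 with the reference fraction).
    """
    cell_ok = counts["cell"].map(mask.retained_cells).fillna(False).to_numpy()
    idx = pd.MultiIndex.from_frame(counts[["cell", "pos"]])
    pos_ok = mask.qualified.reindex(idx).fillna(False).to_numpy()
    live = counts[cell_ok & pos_ok].copy()
    if live.empty:
        return _empty_variant_table()
    ref = _reference_series(reference, live["pos"].unique())
    live["ref"] = live["pos"].map(ref)
    live["depth"] = _depths(live)
    frames = []
    for base in BASES:
        sub = live[(live["ref"] != base) & (live[base] > 0)]
        if sub.empty:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "cell": sub["cell"],
                    "donor": sub["donor"],
                    "site": sub["pos"],
                    "ref": sub["ref"],
                    "alt": base,
                    "alt_reads": sub[base].astype(int),
                    "depth": sub["depth"].astype(int),
                    "heteroplasmy": sub[base] / sub["depth"],
                }
            )
        )
    if not frames:
        return _empty_variant_table()
    vt = pd.concat(frames, ignore_index=True)
    return vt.sort_values(["donor", "cell", "site", "alt"]).reset_index(drop=True)


def _empty_variant_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "cell",
            "donor",
            "site",
            "ref",
            "alt",
            "alt_reads",
            "depth",
            "heteroplasmy",
        ]
    )


def classify_variants(
    vt: pd.DataFrame,
    mask: QCMask,
    cryptic_floor: float = 0.05,
    report_floor: float = 0.10,
    common_donor_count: int = 3,
    min_cells_per_site: int = 10,
) -> pd.DataFrame:
    """Partition called variants into cryptic / shared / common.

    Order of operations: (1) drop variants at sites qualified in fewer than
    ``min_cells_per_site`` retained cells of the donor; (2) variants whose
    (site, alt) occurs in more than ``common_donor_count`` donors are common;
    (3) among the rest, a variant is cryptic iff exactly one cell of its
    donor carries it above ``cryptic_floor``, otherwise shared; (4) only
    variants strictly above ``report_floor`` are retained for reporting.
    """
    if vt.empty:
        out = vt.copy()
        out["classification"] = pd.Series(dtype=object)
        return out
    if vt["donor"].isna().any():
        raise ValueError("variant table contains rows with unknown donor id")
    site_idx = pd.MultiIndex.from_frame(vt[["donor", "site"]])
    n_cells_site = mask.site_cell_counts.reindex(site_idx).fillna(0).to_numpy()
    vt = vt[n_cells_site >= min_cells_per_site].copy()
    if vt.empty:
        vt["classification"] = pd.Series(dtype=object)
        return vt

    # presence (for both the donor-sharing and single-cell rules) means
    # exceeding the cryptic floor; raw error-level reads do not count
    above = vt["heteroplasmy"] > cryptic_floor
    floored = vt[above]
    donors_per = floored.groupby(["site", "alt"])["donor"].nunique()
    cells_per = floored.groupby(["donor", "site", "alt"])["cell"].nunique()
    n_donors = (
        donors_per.reindex(pd.MultiIndex.from_frame(vt[["site", "alt"]]))
        .fillna(0)
        .to_numpy(dtype=int)
    )
    n_cells = (
        cells_per.reindex(pd.MultiIndex.from_frame(vt[["donor", "site", "alt"]]))
        .fillna(0)
        .to_numpy(dtype=int)
    )
    is_common = n_donors > common_donor_count
    classification = np.where(
        is_common,
        "common",
        np.where((n_cells == 1) & above.to_numpy(), "cryptic", "shared"),
    )
    vt["classification"] = classification
    vt = vt[vt["heteroplasmy"] > report_floor]
    return vt.reset_index(drop=True)


def annotate_variants(
    vt: pd.DataFrame,
    annotation: pd.DataFrame,
    species: pd.Series | str | None = None,
    collapse_species: frozenset = frozenset({"mouse", "rat", "pig"}),
) -> pd.DataFrame:
    """Join pathology classes (synonymous / low / high / noncoding) onto calls.

    ``annotation`` has columns pos, ref, alt, class.  Substitutions absent
    from the table get class "unknown".  For species without pathogenicity
    scores (by default mouse, rat, and pig) the low/high classes collapse to
    a single "non-synonymous" label.  ``species`` is either one label for the
    whole table or a donor -> species mapping.
    """
    ann = annotation.drop_duplicates()
    dup = ann.duplicated(subset=["pos", "ref", "alt"], keep=False)
    if dup.any():
        bad = ann[dup].iloc[0]
        raise ValueError(
            "contradictory annotation rows for "
            f"pos={bad['pos']} ref={bad['ref']} alt={bad['alt']}"
        )
    out = vt.merge(
        ann.rename(columns={"pos": "site", "class": "pathology"}),
        on=["site", "ref", "alt"],
        how="left",
    )
    out["pathology"] = out["pathology"].fillna("unknown")
    if species is not None:
        if isinstance(species, str):
            collapse = pd.Series(True, index=out.index) if species in collapse_species else None
        else:
            collapse = out["donor"].map(species).isin(collapse_species)
            collapse = collapse if collapse.any() else None
        if collapse is not None:
            sel = collapse & out["pathology"].isin(["low", "high"])
            out.loc[sel, "pathology"] = "non-synonymous"
    return out


def base_counts_from_alignment(
    path: str,
    cell: str,
    donor: str,
    contig: str = "chrM",
    min_base_quality: int = 30,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Pile up one cell's alignment into the tabular base-count format.

    Reads failing the base-quality cutoff are dropped per-position, and reads
    that are not uniquely aligned (MAPQ 0 or NH tag > 1) are excluded to
    avoid NUMT-driven false heteroplasmies.  Positions are 1-based.
    """
    import pysam

    def _unique(read) -> bool:
        if read.mapping_quality == 0:
            return False
        if read.has_tag("NH") and read.get_tag("NH") > 1:
            return False
        return True

    rows: dict[int, dict[str, int]] = {}
    with pysam.AlignmentFile(path) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name != contig:
                continue
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            if unique_only and not _unique(read):
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                b = seq[qpos].upper()
                if b not in BASES:
                    continue
                tally = rows.setdefault(rpos + 1, {b2: 0 for b2 in BASES})
                tally[b] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "pos"
    df = df.reset_index()
    df.insert(0, "donor", donor)
    df.insert(0, "cell", cell)
    return df[["cell", "donor", "pos", "A", "C", "G", "T"]]
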
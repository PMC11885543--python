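"""Cryptic site frequency spectra and the summary statistics built on them.

The cryptic site frequency spectrum (cSFS) of a donor collects the
heteroplasmies of every cryptic mtDNA mutation found across that donor's
cells and histograms them, with a terminal bin for homoplasmic (operationally
h >= 95%) mutations, which drift can no longer remove.  Comparisons between
spectra use the rank-biserial correlation difference r = f - u (the
probability-scale effect size that a mutation drawn from one spectrum sits
above one drawn from the other) together with a two-sided Mann-Whitney U
test; selection is probed with a Fisher exact test on the
non-synonymous/synonymous split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CrypticSFS",
    "LoadRecord",
    "build_csfs",
    "csfs_from_values",
    "mutation_load",
    "rbc_difference",
    "compare_sfs",
    "dnds_test",
    "pseudobulk_spectrum",
    "homoplasmy_rate",
]


@dataclass
class CrypticSFS:
    """A donor's cryptic heteroplasmies plus their normalized histogram.

    ``bin_edges`` has the equal-width segregating bins on
    ``(floor, homoplasmy_cut)`` followed by the homoplasmic bin
    ``[homoplasmy_cut, 1]``.
    """

    donor: str
    heteroplasmies: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    n_cells: int
    floor: float
    homoplasmy_cut: float
    empty: bool = field(default=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
                "density": self.density,
            }
        )


@dataclass
class LoadRecord:
    """Per-cell mitochondrial mutation load mu^t%."""

    cell: str
    load: float
    threshold: float
    n_contributing: int


def csfs_from_values(
    values,
    donor: str = "",
    floor: float = 0.10,
    bins: int = 20,
    homoplasmy_cut: float = 0.95,
    n_cells: int = 0,
) -> CrypticSFS:
    """Histogram a list of heteroplasmies into a cSFS object.

    Values at or below ``floor`` are rejected (filter upstream); values at or
    above ``homoplasmy_cut`` land in the terminal homoplasmic bin.
    """
    h = np.asarray(values, dtype=float)
    if h.size and (h.min() <= floor or h.max() > 1.0):
        raise ValueError(
            f"heteroplasmies must lie in ({floor}, 1]; got range "
            f"[{h.min():.4g}, {h.max():.4g}]"
        )
    seg_edges = np.linspace(floor, homoplasmy_cut, bins + 1)
    edges = np.append(seg_edges, 1.0)
    counts = np.zeros(bins + 1, dtype=int)
    if h.size:
        homo = h >= homoplasmy_cut
        counts[-1] = int(homo.sum())
        seg_counts, _ = np.histogram(h[~homo], bins=seg_edges)
        counts[:-1] = seg_counts
    total = counts.sum()
    density = counts / total if total else np.zeros_like(counts, dtype=float)
    return CrypticSFS(
        donor=donor,
        heteroplasmies=h,
        bin_edges=edges,
        counts=counts,
        density=density,
        n_cells=n_cells,
        floor=floor,
        homoplasmy_cut=homoplasmy_cut,
        empty=total == 0,
    )


def build_csfs(
    vt: pd.DataFrame,
    donor: str,
    bins: int = 20,
    homoplasmy_cut: float = 0.95,
    floor: float | None = None,
) -> CrypticSFS:
    """Collect a donor's cryptic heteroplasmies from a classified variant table.

    ``floor`` defaults to the smallest power-of-ten-ish report floor implied by
    the data; pass it explicitly when the calling floor is known.  A donor with
    zero cryptic mutations yields an empty, flagged spectrum.
    """
    if donor not in set(vt["donor"]):
        raise KeyError(f"donor {donor!r} not present in variant table")
    sub = vt[(vt["donor"] == donor) & (vt["classification"] == "cryptic")]
    if floor is None:
        floor = 0.10
    n_cells = int(vt.loc[vt["donor"] == donor, "cell"].nunique())
    return csfs_from_values(
        sub["heteroplasmy"].to_numpy(),
        donor=donor,
        floor=floor,
        bins=bins,
        homoplasmy_cut=homoplasmy_cut,
        n_cells=n_cells,
    )


def mutation_load(
    cell_variants: pd.DataFrame,
    t: float = 0.10,
    exclude_synonymous: bool = True,
    include_unknown: bool = True,
) -> LoadRecord:
    """Mitochondrial load mu^t% = sum of heteroplasmies strictly above t.

    Only cryptic mutations contribute; synonymous protein-coding changes are
    excluded by default.  Rows whose pathology class could not be assigned
    ("unknown") count unless ``include_unknown`` is False.
    """
    cells = cell_variants["cell"].unique() if len(cell_variants) else [""]
    if len(cells) > 1:
        raise ValueError("mutation_load expects the variants of a single cell")
    sub = cell_variants
    if "classification" in sub.columns:
        sub = sub[sub["classification"] == "cryptic"]
    if exclude_synonymous and "pathology" in sub.columns:
        sub = sub[sub["pathology"] != "synonymous"]
        if not include_unknown:
            sub = sub[sub["pathology"] != "unknown"]
    h = sub["heteroplasmy"].to_numpy(dtype=float)
    above = h[h > t]
    return LoadRecord(
        cell=str(cells[0]),
        load=float(above.sum()),
        threshold=t,
        n_contributing=int(above.size),
    )


def rbc_difference(g1, g2) -> float:
    """Rank-biserial correlation difference r = f - u between two samples.

    f (u) is the fraction of the |G1| x |G2| pairs in which the G1 (G2)
    member is strictly greater; ties count toward neither, so r ranges over
    [-1, 1] with r = 1 meaning every G1 value exceeds every G2 value.
    """
    a = np.asarray(g1, dtype=float)
    b = np.sort(np.asarray(g2, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("rbc_difference requires two non-empty samples")
    greater = np.searchsorted(b, a, side="left").sum()  # pairs with a > b
    less = (b.size - np.searchsorted(b, a, side="right")).sum()  # a < b
    return float((greater - less) / (a.size * b.size))


def compare_sfs(
    g1,
    g2,
    family_size: int = 1,
) -> dict:
    """RBC-difference plus a two-sided Mann-Whitney U test between two spectra.

    Returns ``{"r", "U", "p", "p_bonferroni"}``.  ``family_size`` applies a
    Bonferroni correction over a family of comparisons (e.g. the three
    pairwise diet-group contrasts).  All-tied inputs give p = 1, r = 0.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("compare_sfs requires two non-empty samples")
    r = rbc_difference(a, b)
    if np.unique(np.concatenate([a, b])).size == 1:
        u = a.size * b.size / 2.0
        p = 1.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        u, p = float(res.statistic), float(res.pvalue)
    return {
        "r": r,
        "U": u,
        "p": p,
        "p_bonferroni": min(1.0, p * family_size),
    }


def dnds_test(
    vt: pd.DataFrame,
    scope: str = "cryptic",
    floor: float = 0.10,
    opportunity: tuple[int, int] | None = None,
) -> dict:
    """Fisher exact test for selection on the non-synonymous/synonymous split.

    Builds the 2x2 table of observed mutations (non-synonymous vs synonymous)
    x (heteroplasmy above vs at-or-below ``floor``) and reports the two-sided
    Fisher exact p.  The dN/dS-style ratio of the above-floor counts is
    normalized by ``opportunity`` = (non-synonymous, synonymous) substitution
    counts from the annotation table's universe when given.  Rows with unknown
    or noncoding pathology are ignored.  Zero synonymous observations above
    the floor leave the ratio undefined (NaN, flagged).
    """
    if scope == "cryptic":
        sub = vt[vt["classification"] == "cryptic"]
    elif scope == "non-cryptic":
        sub = vt[vt["classification"] != "cryptic"]
    elif scope == "all":
        sub = vt
    else:
        raise ValueError(f"unknown scope {scope!r}")
    nonsyn_classes = {"low", "high", "non-synonymous"}
    nonsyn = sub[sub["pathology"].isin(nonsyn_classes)]["heteroplasmy"].to_numpy()
    syn = sub[sub["pathology"] == "synonymous"]["heteroplasmy"].to_numpy()
    table = np.array(
        [
            [int((nonsyn > floor).sum()), int((nonsyn <= floor).sum())],
            [int((syn > floor).sum()), int((syn <= floor).sum())],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    n_above, s_above = table[0, 0], table[1, 0]
    if s_above == 0:
        ratio = float("nan")
    elif opportunity is not None:
        opp_n, opp_s = opportunity
        ratio = (n_above / s_above) / (opp_n / opp_s)
    else:
        ratio = n_above / s_above
    return {
        "table": table,
        "ratio": float(ratio),
        "ratio_defined": s_above > 0,
        "odds_ratio": float(odds),
        "p": float(p),
    }


def pseudobulk_spectrum(
    counts: pd.DataFrame,
    vt: pd.DataFrame,
    bulk_cut: float = 0.005,
) -> dict:
    """Pseudobulk heteroplasmy of each called variant, per donor.

    The pseudobulk h of a (donor, site, alt) variant sums its alt reads over
    all retained cells of the donor and divides by the summed depth at the
    site.  Reports the fraction of distinct variants whose pseudobulk h falls
    below ``bulk_cut`` (invisible to bulk sequencing) and, among those, the
    fraction found in only one cell.
    """
    base_cols = ["A", "C", "G", "T"]
    cc = counts.copy()  # pass QC-retained cells' counts
    cc["depth"] = cc[base_cols].sum(axis=1)
    site_depth = cc.groupby(["donor", "pos"])["depth"].sum()
    rows = []
    for (donor, site, alt), grp in vt.groupby(["donor", "site", "alt"]):
        sub = cc[(cc["donor"] == donor) & (cc["pos"] == site)]
        alt_reads = int(sub[alt].sum())
        total = int(site_depth.loc[(donor, site)])
        rows.append(
            {
                "donor": donor,
                "site": site,
                "alt": alt,
                "pseudobulk_h": alt_reads / total if total else np.nan,
                "n_cells": int(grp["cell"].nunique()),
            }
        )
    per_variant = pd.DataFrame(rows)
    below = per_variant[per_variant["pseudobulk_h"] < bulk_cut]
    frac_below = len(below) / len(per_variant) if len(per_variant) else np.nan
    frac_single = (
        (below["n_cells"] == 1).mean() if len(below) else np.nan
    )
    return {
        "per_variant": per_variant,
        "fraction_below_cut": float(frac_below),
        "fraction_single_cell_among_below": float(frac_single),
    }


def homoplasmy_rate(
    vt: pd.DataFrame,
    qualified_positions: pd.Series,
    cut: float = 0.95,
) -> dict:
    """Per-cell count of near-homoplasmic cryptic mutations per base observed.

    ``qualified_positions`` maps each retained cell to its number of
    positions passing depth QC.  A mutation counts as homoplasmic when its
    heteroplasmy is at least ``cut``.  Returns per-cell rates, per-donor
    means, and the cohort mean.
    """
    cryptic = vt[vt["classification"] == "cryptic"]
    homo = cryptic[cryptic["heteroplasmy"] >= cut]
    counts = homo.groupby("cell").size()
    per_cell = pd.Series(0.0, index=qualified_positions.index)
    shared_idx = counts.index.intersection(per_cell.index)
    per_cell.loc[shared_idx] = (
        counts.loc[shared_idx] / qualified_positions.loc[shared_idx]
    )
    per_cell[qualified_positions == 0] = np.nan
    donor_of = (
        vt.drop_duplicates("cell").set_index("cell")["donor"]
        if len(vt)
        else pd.Series(dtype=object)
    )
    donors = donor_of.reindex(per_cell.index)
    per_donor = per_cell.groupby(donors).mean()
    return {
        "per_cell": per_cell,
        "per_donor": per_donor,
        "cohort_mean": float(per_cell.mean()),
    }
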
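"""Depth/cell QC, read-fraction heteroplasmy, and variant classification."""

import numpy as np
import pandas as pd
import pytest

import mitocrypt as mc
from mitocrypt.variant_calling import EmptyCohortError

from conftest import make_counts_frame


def _cells_counts(qualified_per_cell, depth_hi=300, depth_lo=50):
    """Cohort where cell i has qualified_per_cell[i] positions above depth."""
    rows = []
    n_pos = max(qualified_per_cell) + 10
    for i, q in enumerate(qualified_per_cell):
        for p in range(1, n_pos + 1):
            d = depth_hi if p <= q else depth_lo
            rows.append((f"c{i}", "d0", p, d, 0, 0, 0))
    return make_counts_frame(rows)


class TestQCFilter:
    def test_depth_exactly_at_cutoff_does_not_qualify(self):
        # 200 reads is not "over 200": the cell has zero qualified positions
        rows = [("c0", "d0", p, 200, 0, 0, 0) for p in range(1, 301)]
        rows += [("c1", "d0", p, 201, 0, 0, 0) for p in range(1, 301)]
        mask = mc.qc_filter(make_counts_frame(rows), min_depth=200, min_positions=200)
        assert mask.qualified_per_cell["c0"] == 0
        assert not mask.retained_cells["c0"]
        assert mask.qualified_per_cell["c1"] == 300
        assert mask.retained_cells["c1"]

    def test_zero_variance_cohort_retains_all(self):
        mask = mc.qc_filter(
            _cells_counts([250] * 6), min_depth=200, min_positions=200
        )
        assert mask.retained_cells.all()

    def test_lognormal_outlier_excluded(self):
        # 12 cells at ~1000 qualified positions and one at 10000: by hand,
        # log10 counts are 3.0 (x12) and 4.0; mean=3.077, sd=0.277 -> the
        # outlier deviates by 3.33 sd and is excluded at sigma_mult=3
        q = [1000] * 12 + [10000]
        logs = np.log10(q)
        dev = abs(logs[-1] - logs.mean()) / logs.std()
        assert dev > 3
        mask = mc.qc_filter(_cells_counts(q), min_depth=200, min_positions=200)
        assert not mask.retained_cells["c12"]
        assert mask.retained_cells[[f"c{i}" for i in range(12)]].all()

    def test_all_cells_excluded_raises(self):
        rows = [("c0", "d0", p, 150, 0, 0, 0) for p in range(1, 50)]
        with pytest.raises(EmptyCohortError):
            mc.qc_filter(make_counts_frame(rows))


class TestCallVariants:
    @pytest.mark.parametrize(
        "abc, expected",
        [
            # (A, C, G, T) with ref A -> list of (alt, h)
            ((50, 150, 0, 0), [("C", 0.75)]),
            ((200, 0, 0, 0), []),
            ((100, 60, 40, 0), [("C", 0.30), ("G", 0.20)]),
        ],
    )
    def test_read_fraction_heteroplasmy(self, abc, expected, uniform_ref):
        rows = [("c0", "d0", 1, *abc)]
        # pad so the cell passes QC
        rows += [("c0", "d0", p, 300, 0, 0, 0) for p in range(2, 250)]
        counts = make_counts_frame(rows)
        mask = mc.qc_filter(counts, min_depth=100, min_positions=100)
        vt = mc.call_variants(counts, mask, uniform_ref)
        got = sorted(
            vt[vt["site"] == 1][["alt", "heteroplasmy"]].itertuples(index=False)
        )
        assert [(a, pytest.approx(h)) for a, h in got] == expected

    def test_alt_fractions_and_reference_sum_to_one(self, called):
        grp = called.groupby(["cell", "site"]).agg(
            h_sum=("heteroplasmy", "sum"),
            alt=("alt_reads", "sum"),
            depth=("depth", "first"),
        )
        ref_frac = 1 - grp["alt"] / grp["depth"]
        assert np.allclose(grp["h_sum"] + ref_frac, 1.0)

    def test_missing_reference_is_an_error(self):
        rows = [("c0", "d0", p, 300, 0, 0, 0) for p in range(1, 250)]
        counts = make_counts_frame(rows)
        mask = mc.qc_filter(counts, min_depth=200, min_positions=100)
        with pytest.raises(KeyError, match="position"):
            mc.call_variants(counts, mask, {1: "A"})


def _vt_row(cell, donor, site, h, alt="C"):
    return {
        "cell": cell,
        "donor": donor,
        "site": site,
        "ref": "A",
        "alt": alt,
        "alt_reads": int(1000 * h),
        "depth": 1000,
        "heteroplasmy": h,
    }


def _permissive_mask(vt):
    site_counts = pd.Series(
        99, index=pd.MultiIndex.from_frame(vt[["donor", "site"]].drop_duplicates())
    )
    return mc.QCMask(
        qualified=pd.Series(dtype=bool),
        retained_cells=pd.Series(True, index=vt["cell"].unique()),
        qualified_per_cell=pd.Series(1000, index=vt["cell"].unique()),
        site_cell_counts=site_counts,
        min_depth=200,
        min_positions=200,
        sigma_mult=3.0,
    )


class TestClassifyVariants:
    def test_single_cell_variant_is_cryptic(self):
        vt = pd.DataFrame([_vt_row("c0", "d0", 3243, 0.2)])
        out = mc.classify_variants(vt, _permissive_mask(vt))
        assert list(out["classification"]) == ["cryptic"]

    def test_two_cells_of_one_donor_are_shared(self):
        vt = pd.DataFrame(
            [_vt_row("c0", "d0", 3243, 0.2), _vt_row("c1", "d0", 3243, 0.3)]
        )
        out = mc.classify_variants(vt, _permissive_mask(vt))
        assert list(out["classification"]) == ["shared", "shared"]

    def test_variant_in_four_donors_is_common(self):
        vt = pd.DataFrame(
            [_vt_row(f"c{i}", f"d{i}", 3243, 0.2) for i in range(4)]
        )
        out = mc.classify_variants(vt, _permissive_mask(vt))
        assert (out["classification"] == "common").all()

    def test_site_depth_rule_drops_thin_sites(self):
        vt = pd.DataFrame([_vt_row("c0", "d0", 3243, 0.2)])
        m = _permissive_mask(vt)
        m.site_cell_counts[:] = 5  # fewer than ten well-covered cells
        out = mc.classify_variants(vt, m, min_cells_per_site=10)
        assert len(out) == 0

    def test_report_floor_is_strict(self):
        vt = pd.DataFrame(
            [_vt_row("c0", "d0", 100, 0.10), _vt_row("c0", "d0", 200, 0.101)]
        )
        out = mc.classify_variants(vt, _permissive_mask(vt), report_floor=0.10)
        assert list(out["site"]) == [200]

    def test_partition_is_complete_on_synthetic_cohort(self, classified):
        assert set(classified["classification"]) <= {"cryptic", "shared", "common"}
        assert classified["classification"].notna().all()

    def test_cryptic_uniqueness_on_synthetic_cohort(self, classified):
        cryptic = classified[classified["classification"] == "cryptic"]
        per_variant = cryptic.groupby(["donor", "site", "alt"])["cell"].nunique()
        assert (per_variant == 1).all()


class TestAnnotateVariants:
    def _table(self):
        return pd.DataFrame(
            {
                "pos": [10, 20, 30],
                "ref": ["A", "A", "A"],
                "alt": ["C", "C", "C"],
                "class": ["synonymous", "low", "high"],
            }
        )

    def test_join_and_unknown(self):
        vt = pd.DataFrame(
            [_vt_row("c0", "d0", 10, 0.2), _vt_row("c0", "d0", 99, 0.2)]
        )
        vt["classification"] = "cryptic"
        out = mc.annotate_variants(vt, self._table())
        assert list(out["pathology"]) == ["synonymous", "unknown"]

    def test_mouse_mode_collapses_pathogenicity(self):
        vt = pd.DataFrame(
            [_vt_row("c0", "d0", 20, 0.2), _vt_row("c0", "d0", 30, 0.2)]
        )
        vt["classification"] = "cryptic"
        out = mc.annotate_variants(vt, self._table(), species="mouse")
        assert list(out["pathology"]) == ["non-synonymous", "non-synonymous"]

    def test_per_donor_species_mapping(self):
        vt = pd.DataFrame(
            [_vt_row("c0", "dh", 20, 0.2), _vt_row("c1", "dm", 20, 0.2)]
        )
        vt["classification"] = "cryptic"
        species = pd.Series({"dh": "human", "dm": "mouse"})
        out = mc.annotate_variants(vt, self._table(), species=species)
        assert list(out["pathology"]) == ["low", "non-synonymous"]

    def test_contradictory_annotation_rejected(self):
        tab = self._table()
        tab = pd.concat(
            [tab, pd.DataFrame([{"pos": 10, "ref": "A", "alt": "C", "class": "high"}])]
        )
        vt = pd.DataFrame([_vt_row("c0", "d0", 10, 0.2)])
        with pytest.raises(ValueError, match="contradictory"):
            mc.annotate_variants(vt, tab)


class TestAlignmentIngestion:
    def test_pileup_counts_and_numt_filter(self, tmp_path):
        # three reads covering chrM:1-4; the NH=2 read must be excluded
        sam = "\n".join(
            [
                "@HD\tVN:1.6\tSO:coordinate",
                "@SQ\tSN:chrM\tLN:100",
                "r1\t0\tchrM\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\tNH:i:1",
                "r2\t0\tchrM\t1\t60\t4M\t*\t0\t0\tACGA\tIIII\tNH:i:1",
                "r3\t0\tchrM\t1\t60\t4M\t*\t0\t0\tGGGG\tIIII\tNH:i:2",
                "",
            ]
        )
        path = tmp_path / "cell.sam"
        path.write_text(sam)
        df = mc.base_counts_from_alignment(str(path), cell="c0", donor="d0")
        df = df.set_index("pos")
        assert df.loc[1, "A"] == 2 and df.loc[1, "G"] == 0
        assert df.loc[4, "T"] == 1 and df.loc[4, "A"] == 1
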
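"""Cryptic SFS construction, mutation load, RBC-difference, and selection tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import comb

import mitocrypt as mc
from mitocrypt.sfs_stats import csfs_from_values


class TestBuildCsfs:
    def test_hand_binned_histogram(self):
        # 2 equal-width bins on (0.1, 0.95) plus the homoplasmic bin
        csfs = csfs_from_values([0.12, 0.12, 0.98], floor=0.1, bins=2)
        assert np.allclose(csfs.density, [2 / 3, 0.0, 1 / 3])
        assert csfs.counts.sum() == 3

    def test_single_mutation_is_unit_mass(self):
        csfs = csfs_from_values([0.5], floor=0.1, bins=4)
        assert csfs.density.sum() == 1.0
        assert (csfs.density == 1.0).sum() == 1

    def test_empty_spectrum_is_flagged(self):
        csfs = csfs_from_values([], floor=0.1)
        assert csfs.empty
        assert csfs.density.sum() == 0.0

    def test_value_at_floor_rejected(self):
        with pytest.raises(ValueError):
            csfs_from_values([0.1], floor=0.1)

    def test_histogram_mass_and_count_agree(self, annotated):
        donor = annotated["donor"].iloc[0]
        csfs = mc.build_csfs(annotated, donor, floor=0.10)
        assert csfs.counts.sum() == len(csfs.heteroplasmies)
        if not csfs.empty:
            assert np.isclose(csfs.density.sum(), 1.0)

    def test_unknown_donor_rejected(self, annotated):
        with pytest.raises(KeyError):
            mc.build_csfs(annotated, "nobody")


def _cell_frame(hs, pathology=None, classification="cryptic"):
    df = pd.DataFrame(
        {
            "cell": "c0",
            "heteroplasmy": hs,
            "classification": classification,
        }
    )
    if pathology is not None:
        df["pathology"] = pathology
    return df


class TestMutationLoad:
    @pytest.mark.parametrize(
        "hs, t, expected",
        [
            ([0.05, 0.2, 0.6], 0.10, 0.8),
            ([], 0.10, 0.0),
            ([0.10], 0.10, 0.0),  # Heaviside at equality contributes nothing
        ],
    )
    def test_load_arithmetic(self, hs, t, expected):
        rec = mc.mutation_load(_cell_frame(hs), t=t)
        assert rec.load == pytest.approx(expected)

    def test_synonymous_mutations_excluded(self):
        df = _cell_frame([0.5, 0.4], pathology=["synonymous", "high"])
        assert mc.mutation_load(df).load == pytest.approx(0.4)
        assert mc.mutation_load(df, exclude_synonymous=False).load == pytest.approx(0.9)

    @given(
        hs=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
        t1=st.floats(0.0, 0.9),
        dt=st.floats(0.0, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_h_and_threshold(self, hs, t1, dt):
        base = mc.mutation_load(_cell_frame(hs), t=t1).load
        bigger = mc.mutation_load(_cell_frame([min(h * 1.1, 1.0) for h in hs]), t=t1).load
        assert bigger >= base - 1e-12
        assert mc.mutation_load(_cell_frame(hs), t=t1 + dt).load <= base + 1e-12

    def test_two_cells_rejected(self):
        df = _cell_frame([0.5])
        df2 = pd.concat([df, df.assign(cell="c1")])
        with pytest.raises(ValueError):
            mc.mutation_load(df2)


def _rbc_brute(g1, g2):
    f = sum(a > b for a, b in itertools.product(g1, g2))
    u = sum(b > a for a, b in itertools.product(g1, g2))
    return (f - u) / (len(g1) * len(g2))


class TestRbcDifference:
    def test_hand_example(self):
        assert mc.rbc_difference([0.3, 0.7], [0.2, 0.5]) == pytest.approx(0.5)

    def test_identical_sets_give_zero(self):
        g = [0.1, 0.4, 0.9]
        assert mc.rbc_difference(g, g) == 0.0

    def test_complete_separation_gives_one(self):
        assert mc.rbc_difference([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mc.rbc_difference([], [0.5])

    @given(
        g1=st.lists(st.sampled_from([0.1, 0.2, 0.3, 0.5, 0.9]), min_size=1, max_size=6),
        g2=st.lists(st.sampled_from([0.1, 0.2, 0.3, 0.5, 0.9]), min_size=1, max_size=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_with_ties(self, g1, g2):
        r = mc.rbc_difference(g1, g2)
        assert r == pytest.approx(_rbc_brute(g1, g2))
        assert abs(r) <= 1
        assert mc.rbc_difference(g2, g1) == pytest.approx(-r)


class TestCompareSfs:
    def test_complete_separation_by_ranks(self):
        res = mc.compare_sfs([1, 2, 3], [4, 5, 6])
        assert res["r"] == -1.0
        # U statistic for group1-greater pairs is 0
        assert res["U"] == 0.0

    def test_all_tied_inputs(self):
        res = mc.compare_sfs([0.5] * 4, [0.5] * 3)
        assert res["p"] == 1.0 and res["r"] == 0.0

    def test_bonferroni_family(self):
        res = mc.compare_sfs([1, 2, 3], [1.5, 2.5, 3.5], family_size=3)
        assert res["p_bonferroni"] == pytest.approx(min(1.0, res["p"] * 3))

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(20):
            a, b = rng.uniform(size=1000), rng.uniform(size=1000)
            ps.append(mc.compare_sfs(a, b)["p"])
        assert sum(p > 0.05 for p in ps) >= 18


def _fisher_brute(table):
    """Two-sided Fisher p by hypergeometric enumeration over fixed margins."""
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c

    def pmf(x):
        return (
            comb(r1, x, exact=True)
            * comb(n - r1, c1 - x, exact=True)
            / comb(n, c1, exact=True)
        )

    p_obs = pmf(a)
    return sum(
        pmf(x)
        for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
        if pmf(x) <= p_obs * (1 + 1e-9)
    )


class TestDndsTest:
    def _vt(self, nonsyn_above, nonsyn_below, syn_above, syn_below):
        rows = (
            [("high", 0.5)] * nonsyn_above
            + [("high", 0.05)] * nonsyn_below
            + [("synonymous", 0.5)] * syn_above
            + [("synonymous", 0.05)] * syn_below
        )
        return pd.DataFrame(
            {
                "classification": "cryptic",
                "pathology": [r[0] for r in rows],
                "heteroplasmy": [r[1] for r in rows],
            }
        )

    def test_balanced_table(self):
        res = mc.dnds_test(self._vt(10, 10, 10, 10))
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        vt = self._vt(1, 9, 9, 1)
        res = mc.dnds_test(vt)
        assert res["p"] == pytest.approx(_fisher_brute(res["table"]), rel=1e-6)

    def test_zero_synonymous_above_flagged(self):
        res = mc.dnds_test(self._vt(3, 1, 0, 4))
        assert not res["ratio_defined"]
        assert np.isnan(res["ratio"])

    def test_opportunity_normalization(self):
        res = mc.dnds_test(self._vt(20, 0, 10, 0), opportunity=(200, 100))
        assert res["ratio"] == pytest.approx(1.0)

    def test_type_one_error_calibration(self):
        # classes assigned independently of frequency -> Fisher rejects at
        # most ~5% of the time (the exact test is conservative)
        rng = np.random.default_rng(1)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            n = 80
            path = np.where(rng.random(n) < 0.5, "high", "synonymous")
            h = rng.uniform(0.0, 1.0, n)
            vt = pd.DataFrame(
                {"classification": "cryptic", "pathology": path, "heteroplasmy": h}
            )
            if mc.dnds_test(vt, floor=0.5)["p"] < 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.08


class TestPseudobulk:
    def _cohort(self, n_cells, mutant_h, depth=100):
        counts = pd.DataFrame(
            {
                "cell": [f"c{i}" for i in range(n_cells)],
                "donor": "d0",
                "pos": 7,
                "A": [int(depth * (1 - mutant_h.get(i, 0.0))) for i in range(n_cells)],
                "C": [int(depth * mutant_h.get(i, 0.0)) for i in range(n_cells)],
                "G": 0,
                "T": 0,
            }
        )
        vt = pd.DataFrame(
            [
                {
                    "cell": f"c{i}",
                    "donor": "d0",
                    "site": 7,
                    "ref": "A",
                    "alt": "C",
                    "heteroplasmy": h,
                    "classification": "cryptic",
                }
                for i, h in mutant_h.items()
            ]
        )
        return counts, vt

    def test_single_mutant_cell_dilutes_to_half_percent(self):
        counts, vt = self._cohort(100, {0: 0.5})
        res = mc.pseudobulk_spectrum(counts, vt)
        assert res["per_variant"]["pseudobulk_h"].iloc[0] == pytest.approx(0.005)
        assert res["fraction_below_cut"] == 0.0  # 0.005 is not < 0.005

    def test_homoplasmic_everywhere_gives_one(self):
        counts, vt = self._cohort(10, {i: 1.0 for i in range(10)})
        res = mc.pseudobulk_spectrum(counts, vt)
        assert res["per_variant"]["pseudobulk_h"].iloc[0] == pytest.approx(1.0)

    def test_cryptic_mutations_invisible_in_pseudobulk(self):
        # one cryptic mutation per cell at h = 0.2 in a 100-cell cohort:
        # every pseudobulk h is 0.002 < 0.005 and all are single-cell
        n = 100
        counts_rows, vt_rows = [], []
        for i in range(n):
            for p in range(1, n + 1):
                h = 0.2 if p == i + 1 else 0.0
                counts_rows.append(
                    (f"c{i}", "d0", p, int(100 * (1 - h)), int(100 * h), 0, 0)
                )
            vt_rows.append(
                {
                    "cell": f"c{i}",
                    "donor": "d0",
                    "site": i + 1,
                    "ref": "A",
                    "alt": "C",
                    "heteroplasmy": 0.2,
                    "classification": "cryptic",
                }
            )
        counts = pd.DataFrame(
            counts_rows, columns=["cell", "donor", "pos", "A", "C", "G", "T"]
        )
        res = mc.pseudobulk_spectrum(counts, pd.DataFrame(vt_rows))
        assert np.allclose(res["per_variant"]["pseudobulk_h"], 0.002)
        assert res["fraction_below_cut"] == 1.0
        assert res["fraction_single_cell_among_below"] == 1.0


class TestHomoplasmyRate:
    def test_rate_counts_only_near_homoplasmic(self):
        vt = pd.DataFrame(
            [
                {"cell": "c0", "donor": "d0", "heteroplasmy": 0.96,
                 "classification": "cryptic"},
                {"cell": "c0", "donor": "d0", "heteroplasmy": 0.5,
                 "classification": "cryptic"},
            ]
        )
        qpos = pd.Series({"c0": 10_000})
        res = mc.homoplasmy_rate(vt, qpos)
        assert res["per_cell"]["c0"] == pytest.approx(1e-4)

    def test_young_moran_cohort_has_no_homoplasmies(self, annotated, mask):
        young = annotated[annotated["donor"] == "donor0"]  # age 5 << fixation time
        qpos = mask.qualified_per_cell[mask.retained_cells]
        res = mc.homoplasmy_rate(young, qpos)
        assert res["cohort_mean"] == pytest.approx(0.0)


class TestAgeTrends:
    def test_rbc_difference_increases_with_age_gap(self, annotated):
        donors = {"donor0": 5, "donor1": 25, "donor2": 50, "donor3": 75}
        spectra = {
            d: annotated[
                (annotated["donor"] == d)
                & (annotated["classification"] == "cryptic")
            ]["heteroplasmy"].to_numpy()
            for d in donors
        }
        gaps, rs = [], []
        for a, b in itertools.combinations(donors, 2):
            older, younger = (b, a) if donors[b] > donors[a] else (a, b)
            gaps.append(donors[older] - donors[younger])
            rs.append(mc.rbc_difference(spectra[older], spectra[younger]))
        rho = sps.spearmanr(gaps, rs).statistic
        assert rho > 0

    def test_older_donor_spectrum_sits_higher(self, annotated):
        old = annotated[
            (annotated["donor"] == "donor3")
            & (annotated["classification"] == "cryptic")
        ]["heteroplasmy"]
        young = annotated[
            (annotated["donor"] == "donor1")
            & (annotated["classification"] == "cryptic")
        ]["heteroplasmy"]
        assert mc.rbc_difference(old, young) > 0
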
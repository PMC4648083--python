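"""Phenotype adjustment, accuracy statistics, and experiment designs."""

import numpy as np
import pandas as pd
import pytest

from peagp import simdata
from peagp.datatypes import GenotypeMatrix, PhenotypeTable
from peagp.evalx import (
    CVDesign,
    adjust_phenotypes,
    aggregate_results,
    filter_polymorphic_in_rils,
    metrics,
    phenotypic_prediction_accuracy,
    run_cross_population,
    run_density_series,
    run_size_series,
)
from peagp.popgen import grm_vanraden


def _pheno(rows):
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["individual", "trait", "year", "block", "value"])
    )


class TestAdjustPhenotypes:
    def test_balanced_design_reduces_to_raw_means(self):
        rows = []
        for g in "abc":
            for b in (1, 2):
                rows.append((g, "t", 2007, b, ord(g) + 10 * b))
        adj = adjust_phenotypes(_pheno(rows))
        for g in "abc":
            expect = np.mean([ord(g) + 10, ord(g) + 20])
            assert adj.values_for("t", 2007, [g])[0] == pytest.approx(expect)

    def test_missing_cell_matches_normal_equations_oracle(self):
        # 3 genotypes x 2 blocks, cell (c, 2) missing
        rows = [
            ("a", "t", 2007, 1, 10.0),
            ("a", "t", 2007, 2, 14.0),
            ("b", "t", 2007, 1, 20.0),
            ("b", "t", 2007, 2, 26.0),
            ("c", "t", 2007, 1, 30.0),
        ]
        adj = adjust_phenotypes(_pheno(rows))
        # oracle: solve least squares for mu + g_i + b_j (reference levels a, block1)
        # columns: mu, g_b, g_c, b_2
        X = np.array(
            [
                [1, 0, 0, 0],
                [1, 0, 0, 1],
                [1, 1, 0, 0],
                [1, 1, 0, 1],
                [1, 0, 1, 0],
            ],
            dtype=float,
        )
        y = np.array([10.0, 14.0, 20.0, 26.0, 30.0])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        mu, gb, gc, b2 = beta
        want = {
            "a": mu + b2 / 2,
            "b": mu + gb + b2 / 2,
            "c": mu + gc + b2 / 2,
        }
        for g, w in want.items():
            assert adj.values_for("t", 2007, [g])[0] == pytest.approx(w)

    def test_single_block_passthrough(self):
        rows = [("a", "t", 2003, 1, 5.0), ("b", "t", 2003, 1, 7.0)]
        adj = adjust_phenotypes(_pheno(rows))
        assert adj.values_for("t", 2003, ["a", "b"]).tolist() == [5.0, 7.0]

    def test_zero_block_effect_matches_raw(self, panel, trait):
        pheno, _ = trait
        adj = adjust_phenotypes(pheno)
        gm, _ = panel
        raw = pheno.values_for("t", 2007, gm.individuals)
        got = adj.values_for("t", 2007, gm.individuals)
        np.testing.assert_allclose(got, raw, atol=1e-8)  # balanced blocks


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = metrics(y, y, y_obs_train=np.array([1.0, 2.0, 3.0]), fitted_train=None)
        assert m["accuracy"] == pytest.approx(1.0)
        assert m["q2"] == pytest.approx(1.0)
        assert m["msep"] == 0.0

    def test_hand_computed_four_point_example(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        train_mean = 2.5
        m = metrics(obs, pred, y_obs_train=np.array([2.5, 2.5, 2.5]))
        # manual arithmetic
        assert m["msep"] == pytest.approx(np.mean([0.01, 0.01, 0.04, 0.04]))
        assert m["q2"] == pytest.approx(1 - 0.1 / np.sum((obs - train_mean) ** 2))
        r = np.corrcoef(pred, obs)[0, 1]
        assert m["accuracy"] == pytest.approx(r)

    def test_constant_prediction_flags_undefined_accuracy(self):
        obs = np.array([1.0, 2.0, 3.0])
        m = metrics(obs, np.full(3, 2.0), y_obs_train=obs)
        assert m["undefined_accuracy"]
        assert np.isnan(m["accuracy"])

    def test_r2_from_training_fit(self):
        yt = np.array([1.0, 2.0, 3.0, 5.0])
        ft = np.array([1.1, 2.2, 2.9, 4.6])
        m = metrics(yt, yt, y_obs_train=yt, fitted_train=ft)
        assert m["r2"] == pytest.approx(np.corrcoef(ft, yt)[0, 1] ** 2)


class TestPhenotypicPredictionAccuracy:
    def test_identical_and_flipped_years(self):
        y = np.arange(10, dtype=float)
        assert phenotypic_prediction_accuracy(y, y) == pytest.approx(1.0)
        assert phenotypic_prediction_accuracy(y, -y) == pytest.approx(-1.0)

    def test_independent_years_near_zero(self, rng):
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        assert abs(phenotypic_prediction_accuracy(a, b)) < 0.1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            phenotypic_prediction_accuracy([1.0, 2.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def cv_setup(panel, trait):
    gm, _ = panel
    pheno, _ = trait
    return gm, adjust_phenotypes(pheno)


class TestRunSizeSeries:
    def test_single_rep_bookkeeping(self, cv_setup):
        gm, pheno = cv_setup
        res = run_size_series(
            gm, pheno, CVDesign(n_repetitions=1, test_size=30, train_sizes=(60,), seed=1),
            methods=("gblup",),
        )
        assert len(res) == 1
        assert res.loc[0, "condition"] == "size=60"

    def test_more_training_data_helps_on_noiseless_trait(self, panel):
        gm, _ = panel
        ph, _ = simdata.simulate_trait(
            gm, simdata.TraitSimConfig(n_qtl=50, h2=1.0, seed=50, trait_name="t")
        )
        pheno = adjust_phenotypes(ph)
        res = run_size_series(
            gm,
            pheno,
            CVDesign(n_repetitions=10, test_size=30, train_sizes=(110, 15), seed=2),
            methods=("gblup",),
        )
        means = res.groupby("condition")["accuracy"].mean()
        assert means["size=110"] > means["size=15"]

    def test_deterministic_given_seed(self, cv_setup):
        gm, pheno = cv_setup
        d = CVDesign(n_repetitions=2, test_size=30, train_sizes=(60, 30), seed=5)
        a = run_size_series(gm, pheno, d, methods=("gblup",))
        b = run_size_series(gm, pheno, d, methods=("gblup",))
        pd.testing.assert_frame_equal(a, b)

    def test_nested_training_sets_share_split_hash_per_size(self, cv_setup):
        gm, pheno = cv_setup
        res = run_size_series(
            gm,
            pheno,
            CVDesign(n_repetitions=2, test_size=30, train_sizes=(60, 30), seed=6),
            methods=("gblup", "kplsr"),
        )
        # within a repetition and size, all methods saw the identical split
        for (_, _), grp in res.groupby(["repetition", "condition"]):
            assert grp["split_hash"].nunique() == 1

    def test_insufficient_individuals_rejected(self, cv_setup):
        gm, pheno = cv_setup
        with pytest.raises(ValueError):
            run_size_series(
                gm, pheno, CVDesign(n_repetitions=1, test_size=99, train_sizes=(240,)),
            )


class TestRunDensitySeries:
    def test_own_bin_map_stride_one_identical_to_full(self, cv_setup):
        gm, pheno = cv_setup
        mm = simdata.simulate_map(simdata.SimMapConfig(n_markers=300, seed=11))
        res = run_density_series(
            gm, pheno, mm, strides=(1,),
            design=CVDesign(n_repetitions=2, test_size=30, train_sizes=(80,), seed=3),
            methods=("gblup",),
        )
        piv = res.pivot_table(index="repetition", columns="condition", values="q2_test")
        full = [c for c in piv.columns if c.startswith("full")][0]
        s1 = [c for c in piv.columns if c.startswith("stride1")][0]
        np.testing.assert_allclose(piv[full], piv[s1], atol=1e-12)

    def test_subset_sizes_equal_ceil_bins_over_stride(self, cv_setup):
        gm, pheno = cv_setup
        mm = simdata.simulate_map(simdata.SimMapConfig(n_markers=300, n_bins=90, seed=13))
        gm2, _ = simdata.simulate_panel(mm, simdata.PanelSimConfig(n_accessions=120, seed=14))
        ph, _ = simdata.simulate_trait(
            gm2, simdata.TraitSimConfig(n_qtl=40, h2=0.9, seed=15, trait_name="t")
        )
        res = run_density_series(
            gm2, adjust_phenotypes(ph), mm, strides=(2, 8),
            design=CVDesign(n_repetitions=1, test_size=20, train_sizes=(60,), seed=4),
            methods=("gblup",),
        )
        conds = set(res["condition"])
        assert f"stride2:n_markers={-(-90 // 2)}" in conds
        assert f"stride8:n_markers={-(-90 // 8)}" in conds


@pytest.fixture(scope="module")
def crosspop_data():
    mm = simdata.simulate_map(simdata.SimMapConfig(n_markers=400, seed=61))
    gm, _ = simdata.simulate_panel(
        mm, simdata.PanelSimConfig(n_accessions=120, seed=62)
    )
    ph, _truth = simdata.simulate_trait(
        gm,
        simdata.TraitSimConfig(
            n_qtl=80, h2=0.98, seed=63, trait_name="t", years=(2007,)
        ),
    )
    plan = simdata.CrossPlan(
        parent_pairs=[
            (gm.individuals[0], gm.individuals[60]),
            (gm.individuals[10], gm.individuals[90]),
        ],
        n_ril_per_cross=60,
        seed=64,
    )
    rils, pops = simdata.simulate_ril_populations(gm, mm, plan)
    # RILs carry the same trait architecture as their panel parents
    ph2 = simdata.simulate_trait_from_truth(
        rils, _truth, year=2011, h2=0.98, trait_name="t", seed=65
    )
    return gm, adjust_phenotypes(ph), rils, adjust_phenotypes(ph2), pops


class TestCrossPopulation:
    def test_polymorphic_filter_matches_bruteforce(self, crosspop_data):
        gm, _, rils, _, pops = crosspop_data
        kept = set(filter_polymorphic_in_rils(gm, rils, pops))
        for j, m in enumerate(rils.markers):
            poly_any = False
            for p in np.unique(pops):
                sub = rils.codes[pops == p, j]
                poly_any |= len(np.unique(sub)) >= 2
            assert (m in kept) == poly_any

    def test_positive_transfer_and_full_panel_training(self, crosspop_data):
        gm, pheno, rils, pheno_rils, pops = crosspop_data
        res = run_cross_population(
            gm, pheno, rils, pheno_rils, pops,
            sizes=("all", 50), methods=("gblup",), n_repetitions=3,
        )
        full = res[res.condition == "train_size=all"]
        assert len(full) == 1  # deterministic single run for the full panel
        assert res["accuracy"].mean() > 0

    def test_marker_set_mismatch_rejected(self, crosspop_data):
        gm, pheno, rils, pheno_rils, pops = crosspop_data
        bad = rils.select_markers(rils.markers[:100])
        with pytest.raises(ValueError):
            filter_polymorphic_in_rils(gm, bad, pops)


def test_aggregation_matches_bruteforce(cv_setup):
    gm, pheno = cv_setup
    res = run_size_series(
        gm, pheno, CVDesign(n_repetitions=3, test_size=30, train_sizes=(60, 30), seed=8),
        methods=("gblup",),
    )
    agg = aggregate_results(res)
    for _, row in agg.iterrows():
        sub = res[(res.method == row.method) & (res.condition == row.condition)]
        assert row["accuracy_mean"] == pytest.approx(sub["accuracy"].mean())
        assert row["accuracy_std"] == pytest.approx(sub["accuracy"].std())
        assert row["accuracy_count"] == len(sub)
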
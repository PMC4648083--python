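"""Phenotype adjustment, prediction metrics, and the benchmark experiments.

Experiments mirror a panel-based genomic-prediction study design: repeated
random train/test splits with a fixed test set per repetition, a descending
series of nested training sizes, a marker-density series built by bin
thinning, a comparison of CDmean-optimized vs random training sets, and a
panel-to-RIL cross-population experiment.  All results come out as tidy
tables, one row per (method, trait, condition, repetition).
"""

from __future__ import annotations

import hashlib
import zlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .datatypes import GenotypeMatrix, MarkerMap, PhenotypeTable, RelationshipMatrix
from .genio import marker_stats
from .models import make_model, predict_gebv, FittedModel
from .popgen import grm_vanraden, thin_by_bins
from .trainsel import CDConfig, cdmean, optimize_training_set

logger = logging.getLogger(__name__)

__all__ = [
    "CVDesign",
    "adjust_phenotypes",
    "metrics",
    "phenotypic_prediction_accuracy",
    "run_size_series",
    "run_density_series",
    "run_cdmean_vs_random",
    "filter_polymorphic_in_rils",
    "run_cross_population",
    "aggregate_results",
]

RESULT_COLUMNS = [
    "method",
    "trait",
    "condition",
    "repetition",
    "accuracy",
    "accuracy_cross",
    "r2_train",
    "q2_test",
    "msep",
    "split_hash",
]


@dataclass
class CVDesign:
    n_repetitions: int = 200
    test_size: int = 99
    train_sizes: tuple = (240, 210, 180, 150, 120, 90, 60, 30, 15)
    nested: bool = True
    seed: int = 0

    def __post_init__(self):
        sizes = tuple(self.train_sizes)
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("train_sizes must be strictly decreasing")
        self.train_sizes = sizes


def adjust_phenotypes(raw: PhenotypeTable) -> PhenotypeTable:
    """Two-way (genotype + block) least-squares means per trait and year.

    Balanced designs reduce to the raw mean over blocks; a single-block
    trial passes through with a warning.  Genotypes absent from every block
    of a trait/year are simply not represented in that trait/year.
    """
    out_rows = []
    for (trait, year), sub in raw.table.groupby(["trait", "year"], sort=True):
        blocks = sub["block"].unique()
        if len(blocks) < 2:
            logger.warning("trait %s year %s has one block; pass-through means", trait, year)
            means = sub.groupby("individual")["value"].mean()
        else:
            df = sub.rename(columns={"individual": "genotype"})
            fit = smf.ols("value ~ C(genotype) + C(block)", data=df).fit()
            genotypes = df["genotype"].unique()
            grid = pd.DataFrame(
                [(g, b) for g in genotypes for b in blocks], columns=["genotype", "block"]
            )
            pred = fit.predict(grid)
            grid["pred"] = np.asarray(pred)
            means = grid.groupby("genotype")["pred"].mean()
        for ind, v in means.items():
            out_rows.append((ind, trait, year, 1, float(v)))
    return PhenotypeTable(
        pd.DataFrame(out_rows, columns=["individual", "trait", "year", "block", "value"])
    )


def metrics(y_obs_test, gebv_test, y_obs_train=None, fitted_train=None) -> dict:
    """Accuracy (Pearson r), R2 on the training fit, predictive Q2, and MSEP.

    Q2 = 1 - sum (y_test - gebv)^2 / sum (y_test - mean(y_train))^2, the
    predictive convention with the training mean as reference.  Accuracy is
    reported as NaN (with a flag) when the observed test values have zero
    variance.
    """
    y = np.asarray(y_obs_test, dtype=float)
    g = np.asarray(gebv_test, dtype=float)
    if len(y) != len(g):
        raise ValueError("length mismatch between observations and GEBVs")
    if len(y) < 3:
        raise ValueError("need at least 3 test observations")
    out = {"undefined_accuracy": False}
    if np.var(y) == 0 or np.var(g) == 0:
        out["accuracy"] = np.nan
        out["undefined_accuracy"] = True
    else:
        out["accuracy"] = float(np.corrcoef(g, y)[0, 1])
    out["msep"] = float(np.mean((g - y) ** 2))
    if y_obs_train is not None:
        ref = float(np.mean(y_obs_train))
        tss = float(np.sum((y - ref) ** 2))
        out["q2"] = 1.0 - float(np.sum((y - g) ** 2)) / tss if tss > 0 else np.nan
    else:
        out["q2"] = np.nan
    if fitted_train is not None and y_obs_train is not None:
        yt = np.asarray(y_obs_train, dtype=float)
        ft = np.asarray(fitted_train, dtype=float)
        if np.var(yt) > 0 and np.var(ft) > 0:
            out["r2"] = float(np.corrcoef(ft, yt)[0, 1] ** 2)
        else:
            out["r2"] = np.nan
    else:
        out["r2"] = np.nan
    return out


def phenotypic_prediction_accuracy(y_yearA, y_yearB, test_idx=None) -> float:
    """Pearson correlation of two years' phenotypes over the test set."""
    a = np.asarray(y_yearA, dtype=float)
    b = np.asarray(y_yearB, dtype=float)
    if test_idx is not None:
        a, b = a[test_idx], b[test_idx]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired observations")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def _split_hash(train_ids, test_ids) -> str:
    h = hashlib.sha1()
    h.update("|".join(map(str, train_ids)).encode())
    h.update(b"##")
    h.update("|".join(map(str, test_ids)).encode())
    return h.hexdigest()[:12]


def _fit_and_score(
    method,
    gm_train,
    gm_test,
    y_train,
    y_test_same,
    y_test_cross,
    seed,
    model_overrides=None,
):
    est = make_model(method, seed=seed, **(model_overrides or {}).get(method, {}))
    model = FittedModel(method=method, estimator=est, marker_ids=gm_train.markers)
    est.fit(gm_train.codes.astype(float), y_train)
    gebv_test = predict_gebv(model, gm_test)
    fitted_train = est.predict(gm_train.codes.astype(float))
    m = metrics(y_test_same, gebv_test, y_train, fitted_train)
    cross = np.nan
    if y_test_cross is not None and np.isfinite(y_test_cross).sum() >= 3:
        ok = np.isfinite(y_test_cross)
        if np.var(y_test_cross[ok]) > 0 and np.var(gebv_test[ok]) > 0:
            cross = float(np.corrcoef(gebv_test[ok], y_test_cross[ok])[0, 1])
    return m, cross


def _complete_subset(pheno, trait, year, gm):
    """Individual ids having both a genotype and a phenotype for trait/year."""
    vals = pheno.values_for(trait, year, gm.individuals)
    return gm.individuals[np.isfinite(vals)]


def run_size_series(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    design: CVDesign,
    methods=("gblup",),
    trait=None,
    train_year=None,
    cross_year=None,
    model_overrides=None,
) -> pd.DataFrame:
    """Training-size series: fixed test set per repetition, nested train sets."""
    gm.require_complete("cross-validation")
    traits = [trait] if trait else pheno.traits
    rows = []
    for tr_name in traits:
        years = pheno.years
        y_a = train_year if train_year is not None else years[0]
        y_b = cross_year if cross_year is not None else (years[1] if len(years) > 1 else None)
        keep = _complete_subset(pheno, tr_name, y_a, gm)
        sub = gm.select_individuals(keep)
        n = sub.n_individuals
        need = max(design.train_sizes) + design.test_size
        if need > n:
            raise ValueError(f"need {need} phenotyped individuals, have {n}")
        y_all = pheno.values_for(tr_name, y_a, sub.individuals)
        y_all_b = pheno.values_for(tr_name, y_b, sub.individuals) if y_b is not None else None
        for rep in range(design.n_repetitions):
            rng = np.random.default_rng((design.seed, rep, zlib.crc32(str(tr_name).encode()) % 2**16))
            perm = rng.permutation(n)
            test_pos = perm[: design.test_size]
            pool = perm[design.test_size:]
            gm_test = sub.select_individuals(sub.individuals[test_pos])
            for size in design.train_sizes:
                train_pos = (
                    pool[:size] if design.nested else rng.choice(pool, size, replace=False)
                )
                gm_tr = sub.select_individuals(sub.individuals[train_pos])
                shash = _split_hash(sub.individuals[train_pos], sub.individuals[test_pos])
                for method in methods:
                    m, cross = _fit_and_score(
                        method,
                        gm_tr,
                        gm_test,
                        y_all[train_pos],
                        y_all[test_pos],
                        None if y_all_b is None else y_all_b[test_pos],
                        seed=rep * 1000 + size,
                        model_overrides=model_overrides,
                    )
                    rows.append(
                        (
                            method,
                            tr_name,
                            f"size={size}",
                            rep,
                            m["accuracy"],
                            cross,
                            m["r2"],
                            m["q2"],
                            m["msep"],
                            shash,
                        )
                    )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_density_series(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    marker_map: MarkerMap,
    strides=(1, 2, 3, 4, 5, 6, 7, 8),
    design: CVDesign = None,
    methods=("gblup",),
    trait=None,
    train_year=None,
    model_overrides=None,
) -> pd.DataFrame:
    """Marker-density series: full set plus bin-thinned subsets per stride.

    The same train/test split is reused across densities within a
    repetition; conditions are labelled by the retained marker count.
    """
    gm.require_complete("cross-validation")
    design = design or CVDesign()
    stats = marker_stats(gm)
    subsets = {"full": gm.markers}
    for k in strides:
        kept = thin_by_bins(gm, marker_map, stats, stride=k)
        subsets[f"stride{k}"] = kept
    traits = [trait] if trait else pheno.traits
    rows = []
    size = design.train_sizes[0]
    for tr_name in traits:
        y_a = train_year if train_year is not None else pheno.years[0]
        keep = _complete_subset(pheno, tr_name, y_a, gm)
        sub = gm.select_individuals(keep)
        n = sub.n_individuals
        if size + design.test_size > n:
            raise ValueError(f"need {size + design.test_size} individuals, have {n}")
        y_all = pheno.values_for(tr_name, y_a, sub.individuals)
        for rep in range(design.n_repetitions):
            rng = np.random.default_rng((design.seed, rep, zlib.crc32(str(tr_name).encode()) % 2**16))
            perm = rng.permutation(n)
            test_pos = perm[: design.test_size]
            train_pos = perm[design.test_size : design.test_size + size]
            shash = _split_hash(sub.individuals[train_pos], sub.individuals[test_pos])
            for label, markers in subsets.items():
                gm_tr = sub.select_individuals(sub.individuals[train_pos]).select_markers(markers)
                gm_te = sub.select_individuals(sub.individuals[test_pos]).select_markers(markers)
                for method in methods:
                    m, _ = _fit_and_score(
                        method,
                        gm_tr,
                        gm_te,
                        y_all[train_pos],
                        y_all[test_pos],
                        None,
                        seed=rep * 1000,
                        model_overrides=model_overrides,
                    )
                    rows.append(
                        (
                            method,
                            tr_name,
                            f"{label}:n_markers={len(markers)}",
                            rep,
                            m["accuracy"],
                            np.nan,
                            m["r2"],
                            m["q2"],
                            m["msep"],
                            shash,
                        )
                    )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_cdmean_vs_random(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    G: RelationshipMatrix,
    design: CVDesign = None,
    lambdas=(0.01, 0.4),
    methods=("gblup",),
    trait=None,
    train_year=None,
    n_iter: int = 2000,
    model_overrides=None,
) -> pd.DataFrame:
    """CDmean-optimized vs random training sets, same test set per repetition.

    The returned table carries an extra ``set_cdmean`` column: the CDmean of
    each training set for the within-panel targets at the row's lambda, so
    the optimizer's criterion gain is visible next to the realized accuracy.
    """
    gm.require_complete("cross-validation")
    design = design or CVDesign(n_repetitions=50)
    traits = [trait] if trait else pheno.traits
    rows = []
    for tr_name in traits:
        y_a = train_year if train_year is not None else pheno.years[0]
        keep = _complete_subset(pheno, tr_name, y_a, gm)
        sub = gm.select_individuals(keep)
        Gs = G.subset(sub.individuals)
        n = sub.n_individuals
        y_all = pheno.values_for(tr_name, y_a, sub.individuals)
        for rep in range(design.n_repetitions):
            rng = np.random.default_rng((design.seed, rep, zlib.crc32(str(tr_name).encode()) % 2**16))
            perm = rng.permutation(n)
            test_pos = perm[: design.test_size]
            test_ids = sub.individuals[test_pos]
            pool = perm[design.test_size:]
            gm_test = sub.select_individuals(test_ids)
            eligible = set(sub.individuals) - set(test_ids)

            def set_cdmean(train_ids, size, lam):
                targets = eligible - set(train_ids)
                if not targets or size == len(eligible):
                    targets = set(sub.individuals) - set(train_ids)
                return cdmean(Gs, list(train_ids), sorted(targets), lam)

            for size in design.train_sizes:
                random_ids = sub.individuals[pool[:size]]
                sets = {"random": random_ids}
                for lam in lambdas:
                    cfg = CDConfig(lam=lam, n_iter=n_iter, seed=int(rng.integers(2**31)))
                    opt_ids, _ = optimize_training_set(
                        Gs, size, mode="within_panel", cfg=cfg, test_ids=test_ids
                    )
                    sets[f"cdmean(lam={lam})"] = opt_ids
                for sampling, train_ids in sets.items():
                    train_pos = np.array(
                        [np.flatnonzero(sub.individuals == i)[0] for i in train_ids]
                    )
                    gm_tr = sub.select_individuals(train_ids)
                    shash = _split_hash(train_ids, test_ids)
                    lam_of_row = (
                        float(sampling.split("lam=")[1].rstrip(")"))
                        if "lam=" in sampling
                        else lambdas[0]
                    )
                    cd_val = set_cdmean(train_ids, size, lam_of_row)
                    for method in methods:
                        m, _ = _fit_and_score(
                            method,
                            gm_tr,
                            gm_test,
                            y_all[train_pos],
                            y_all[test_pos],
                            None,
                            seed=rep * 1000 + size,
                            model_overrides=model_overrides,
                        )
                        rows.append(
                            (
                                method,
                                tr_name,
                                f"size={size},sampling={sampling}",
                                rep,
                                m["accuracy"],
                                np.nan,
                                m["r2"],
                                m["q2"],
                                m["msep"],
                                shash,
                                cd_val,
                            )
                        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS + ["set_cdmean"])


def filter_polymorphic_in_rils(
    gm_panel: GenotypeMatrix, gm_rils: GenotypeMatrix, populations
) -> np.ndarray:
    """Markers polymorphic (>= 2 distinct codes) within at least one RIL population."""
    if list(gm_panel.markers) != list(gm_rils.markers):
        raise ValueError("panel and RIL matrices must share the same marker set")
    populations = np.asarray(populations, dtype=object)
    keep = np.zeros(gm_rils.n_markers, dtype=bool)
    for pop in pd.unique(populations):
        sub = gm_rils.codes[populations == pop]
        lo = sub.min(axis=0)
        hi = sub.max(axis=0)
        keep |= lo != hi
    return gm_panel.markers[keep]


def run_cross_population(
    gm_panel: GenotypeMatrix,
    pheno_panel: PhenotypeTable,
    gm_rils: GenotypeMatrix,
    pheno_rils: PhenotypeTable,
    populations,
    sizes=("all", 250, 150, 50),
    methods=("gblup",),
    cfg: CDConfig | None = None,
    n_repetitions: int = 50,
    trait=None,
    train_year=None,
    test_year=None,
    model_overrides=None,
) -> pd.DataFrame:
    """Panel-to-RIL prediction with full or CDmean-subset training sets.

    Markers are first restricted to those polymorphic in at least one RIL
    population; training phenotypes come from the panel year, scoring
    phenotypes from the RIL year.  Subset training sets are re-optimized in
    ``cross_population`` mode each repetition; the full-panel condition is a
    single training set with repetitions only over sampler seeds.
    """
    cfg = cfg or CDConfig(lam=0.01)
    poly = filter_polymorphic_in_rils(gm_panel, gm_rils, populations)
    panel = gm_panel.select_markers(poly)
    rils = gm_rils.select_markers(poly)
    G = grm_vanraden(panel)
    traits = [trait] if trait else pheno_panel.traits
    rows = []
    for tr_name in traits:
        y_a = train_year if train_year is not None else pheno_panel.years[0]
        y_b = test_year if test_year is not None else pheno_rils.years[0]
        keep = _complete_subset(pheno_panel, tr_name, y_a, panel)
        sub = panel.select_individuals(keep)
        Gs = G.subset(sub.individuals)
        y_train_all = pheno_panel.values_for(tr_name, y_a, sub.individuals)
        y_test = pheno_rils.values_for(tr_name, y_b, rils.individuals)
        ok = np.isfinite(y_test)
        rils_t = rils.select_individuals(rils.individuals[ok])
        y_test = y_test[ok]
        for size in sizes:
            reps = 1 if size == "all" else n_repetitions
            for rep in range(reps):
                if size == "all":
                    train_ids = sub.individuals
                else:
                    c = CDConfig(
                        lam=cfg.lam,
                        n_iter=cfg.n_iter,
                        seed=(cfg.seed + 7919 * rep) % 2**31,
                    )
                    train_ids, _ = optimize_training_set(
                        Gs, int(size), mode="cross_population", cfg=c
                    )
                pos = np.array([np.flatnonzero(sub.individuals == i)[0] for i in train_ids])
                gm_tr = sub.select_individuals(train_ids)
                shash = _split_hash(train_ids, rils_t.individuals)
                for method in methods:
                    m, _ = _fit_and_score(
                        method,
                        gm_tr,
                        rils_t,
                        y_train_all[pos],
                        y_test,
                        None,
                        seed=rep * 1000 + (0 if size == "all" else int(size)),
                        model_overrides=model_overrides,
                    )
                    rows.append(
                        (
                            method,
                            tr_name,
                            f"train_size={size}",
                            rep,
                            m["accuracy"],
                            np.nan,
                            m["r2"],
                            m["q2"],
                            m["msep"],
                            shash,
                        )
                    )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def aggregate_results(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation over repetitions per (method, trait, condition)."""
    agg = (
        results.groupby(["method", "trait", "condition"], sort=True)[
            ["accuracy", "accuracy_cross", "r2_train", "q2_test", "msep"]
        ]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    agg.columns = ["_".join(c).rstrip("_") for c in agg.columns]
    return agg
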
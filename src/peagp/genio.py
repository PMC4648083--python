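"""Genotype, map, and phenotype file I/O; QC filters; k-NN imputation.

CSV genotype dialect: header row of marker ids, first column the individual
id, cells in {0, 1, 2, NA}.  VCF import maps diploid GT calls 0/0 -> 0,
0/1 -> 1, 1/1 -> 2 and missing -> the missing sentinel; non-biallelic
records are skipped with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, MarkerMap, MarkerStats, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_phenotypes",
    "write_phenotypes",
    "marker_stats",
    "qc_filter",
    "impute_knn",
]


def read_genotypes(path, dialect: str = "csv") -> GenotypeMatrix:
    if dialect == "csv":
        return _read_genotypes_csv(path)
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    codes = np.empty(df.shape, dtype=np.int8)
    valid = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING}
    arr = df.to_numpy()
    for cell in np.unique(arr):
        if cell not in valid:
            raise ValueError(f"malformed genotype cell {cell!r} in {path}")
    for key, val in valid.items():
        codes[arr == key] = val
    return GenotypeMatrix(df.index.to_numpy(object), df.columns.to_numpy(object), codes)


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = np.asarray(vcf.samples, dtype=object)
    markers, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping non-biallelic VCF record %s:%s", var.CHROM, var.POS)
            continue
        gts = np.asarray(var.genotype.array())[:, :2]
        col = gts.sum(axis=1).astype(np.int8)
        col[(gts < 0).any(axis=1)] = MISSING
        markers.append(var.ID or f"{var.CHROM}_{var.POS}")
        columns.append(col)
    codes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, np.asarray(markers, dtype=object), codes)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = gm.to_dataframe().astype(object)
    df[gm.missing_mask] = "NA"
    df.to_csv(path)


def read_map(path) -> MarkerMap:
    df = pd.read_csv(path)
    return MarkerMap(df[["marker", "lg", "pos_cm"]])


def write_map(mm: MarkerMap, path) -> None:
    mm.table[["marker", "lg", "pos_cm"]].to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path))


def write_phenotypes(pt: PhenotypeTable, path) -> None:
    pt.table.to_csv(path, index=False)


def marker_stats(gm: GenotypeMatrix) -> MarkerStats:
    """Per-marker MAF, missing rate and heterozygosity from non-missing calls.

    MAF = min(p, 1-p) with p = (2*n2 + n1) / (2*(n0 + n1 + n2)); a marker
    with no non-missing call gets NaN statistics.
    """
    codes = gm.codes
    obs = codes != MISSING
    n_obs = obs.sum(axis=0).astype(float)
    n1 = (codes == 1).sum(axis=0)
    n2 = (codes == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, (2.0 * n2 + n1) / (2.0 * n_obs), np.nan)
        maf = np.minimum(p, 1.0 - p)
        het = np.where(n_obs > 0, n1 / n_obs, np.nan)
    missing_rate = (codes == MISSING).sum(axis=0) / gm.n_individuals
    n0 = (codes == 0).sum(axis=0)
    mono = ((n0 > 0).astype(int) + (n1 > 0).astype(int) + (n2 > 0).astype(int)) <= 1
    table = pd.DataFrame(
        {
            "marker": gm.markers,
            "maf": maf,
            "missing_rate": missing_rate,
            "het_rate": het,
            "monomorphic": mono,
        }
    )
    return MarkerStats(table)


def _individual_het(codes: np.ndarray) -> np.ndarray:
    obs = (codes != MISSING).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(obs > 0, (codes == 1).sum(axis=1) / obs, np.nan)


def qc_filter(
    gm: GenotypeMatrix,
    max_marker_missing: float = 0.1,
    max_individual_het: float = 0.05,
    min_maf: float | None = None,
    marker_het: bool = False,
):
    """Apply the panel QC filters; returns ``(filtered_matrix, report)``.

    Removal is at-threshold inclusive: markers with missing rate
    >= ``max_marker_missing`` and individuals with heterozygosity
    >= ``max_individual_het`` are dropped; markers with MAF < ``min_maf``
    are dropped only when ``min_maf`` is given (low-MAF markers are kept by
    default).  ``marker_het`` additionally applies the heterozygosity
    threshold to markers.

    Passes alternate between marker and individual removal until a fixed
    point: removing high-heterozygosity individuals can change marker
    missing rates, so a single pass is not idempotent in general.
    """
    for thr in (max_marker_missing, max_individual_het):
        if not (0.0 <= thr <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
    report = {"removed_markers": [], "removed_individuals": []}

    out = gm
    while True:
        changed = False
        stats = marker_stats(out)
        drop = stats.table["missing_rate"].to_numpy() >= max_marker_missing
        reasons = np.array(["missing_rate"] * out.n_markers, dtype=object)
        if min_maf is not None:
            low = (stats.table["maf"].to_numpy() < min_maf) & ~drop
            reasons[low] = "maf"
            drop |= low
        if marker_het:
            high = (stats.table["het_rate"].to_numpy() >= max_individual_het) & ~drop
            reasons[high] = "het_rate"
            drop |= high
        if drop.any():
            changed = True
            for m, why in zip(out.markers[drop], reasons[drop]):
                report["removed_markers"].append((m, why))
            if drop.all():
                raise ValueError("all markers removed; binding filter: marker missing/MAF")
            out = out.select_markers(out.markers[~drop])

        het = _individual_het(out.codes)
        drop_ind = het >= max_individual_het
        if drop_ind.any():
            changed = True
            for ind in out.individuals[drop_ind]:
                report["removed_individuals"].append((ind, "heterozygosity"))
            if drop_ind.all():
                raise ValueError(
                    "all individuals removed; binding filter: heterozygosity"
                )
            out = out.select_individuals(out.individuals[~drop_ind])
        if not changed:
            break
    out = GenotypeMatrix(out.individuals, out.markers, out.codes.copy(), "filtered")
    return out, report


def impute_knn(gm: GenotypeMatrix, k: int = 5, eps: float = 1e-6) -> GenotypeMatrix:
    """k-nearest-neighbour imputation of missing genotype calls.

    Distance between individuals is the mean squared code difference over
    their shared non-missing markers.  Each missing cell is replaced by the
    1/(d+eps)-weighted mean of the codes of the k nearest individuals with a
    call at that marker, rounded to the nearest valid code; ties in distance
    are broken by individual order.  If no individual has a call at the
    marker, the (rounded) marker mean is used.
    """
    if gm.is_complete():
        out = GenotypeMatrix(gm.individuals, gm.markers, gm.codes.copy(), "imputed")
        return out
    codes = gm.codes.astype(float)
    obs = gm.codes != MISSING
    X0 = np.where(obs, codes, 0.0)
    M = obs.astype(float)
    shared = M @ M.T
    if (shared[~np.eye(len(M), dtype=bool)] < 1).any():
        raise ValueError("some individual pairs share no non-missing marker")
    sq = X0**2
    ssd = sq @ M.T + M @ sq.T - 2.0 * X0 @ X0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        D = ssd / shared
    out_codes = gm.codes.copy()
    n = gm.n_individuals
    others = {
        i: np.lexsort((np.delete(np.arange(n), i), D[i, np.delete(np.arange(n), i)]))
        for i in set(np.where(~obs)[0])
    }
    neighbor_order = {
        i: np.delete(np.arange(n), i)[order] for i, order in others.items()
    }
    marker_mean = np.nanmean(np.where(obs, codes, np.nan), axis=0)
    for i, j in zip(*np.where(~obs)):
        ranked = neighbor_order[i]  # all others by (distance, id order)
        near = ranked[:k]
        donors = near[obs[near, j]]
        if len(donors) == 0:
            # expand past k until a donor with a call at this marker appears
            for cand in ranked[k:]:
                if obs[cand, j]:
                    donors = np.array([cand])
                    break
        if len(donors) == 0:
            if np.isnan(marker_mean[j]):
                raise ValueError(f"marker {gm.markers[j]!r} has no observed call")
            out_codes[i, j] = _round_code(float(marker_mean[j]))
            continue
        w = 1.0 / (D[i, donors] + eps)
        out_codes[i, j] = _round_code(float(np.sum(w * codes[donors, j]) / np.sum(w)))
    return GenotypeMatrix(gm.individuals, gm.markers, out_codes, "imputed")


def _round_code(x: float) -> np.int8:
    return np.int8(min(2, max(0, int(round(x)))))
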
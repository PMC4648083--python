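"""Genomic relationship matrix, pairwise LD, LD-decay fit, and bin thinning.

The relationship matrix follows VanRaden's first method with sample allele
frequencies: G = W W' / (2 * sum_j p_j (1 - p_j)), W the matrix of codes
centered by 2 p_j, monomorphic markers excluded.  LD is the squared Pearson
correlation of genotype codes; its decay with genetic distance d is fitted
with the sample-size-aware expectation of r^2 for a recombination-scaled
distance C = rho * d,

    E[r^2](C) = (10 + C) / ((2 + C)(11 + C))
                * (1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C))),

which falls from ~10/22 at C = 0 to the 1/n sampling floor at large C.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .datatypes import GenotypeMatrix, MarkerMap, MarkerStats, RelationshipMatrix

__all__ = [
    "grm_vanraden",
    "ld_r2",
    "expected_r2",
    "fit_hill_weir",
    "HillWeirFit",
    "assign_bins",
    "thin_by_bins",
]


def grm_vanraden(gm: GenotypeMatrix, ridge: float = 1e-6) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix with sample frequencies.

    A ridge ``ridge * I`` is added if the smallest eigenvalue is <= 0 so the
    matrix can be inverted downstream.
    """
    gm.require_complete("GRM")
    codes = gm.codes.astype(float)
    p = codes.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic markers for a GRM")
    W = codes[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    if np.linalg.eigvalsh(G)[0] <= 0:
        G = G + ridge * np.eye(len(G))
    return RelationshipMatrix(gm.individuals, G, allele_freqs=p)


def ld_r2(gm: GenotypeMatrix, marker_map: MarkerMap, max_dist_cM: float = np.inf) -> pd.DataFrame:
    """Pairwise LD r^2 for within-linkage-group marker pairs.

    Returns a table (marker_a, marker_b, lg, distance_cm, r2); pairs where
    either marker has zero variance are skipped.
    """
    gm.require_complete("LD")
    order = {m: i for i, m in enumerate(gm.markers)}
    rows = []
    t = marker_map.table
    for lg in marker_map.linkage_groups:
        sub = t[t["lg"] == lg]
        ids = [m for m in sub["marker"] if m in order]
        pos = sub.set_index("marker").loc[ids, "pos_cm"].to_numpy(float)
        cols = gm.codes[:, [order[m] for m in ids]].astype(float)
        sd = cols.std(axis=0)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        ids_ok = np.asarray(ids, dtype=object)[ok]
        pos_ok = pos[ok]
        corr = np.corrcoef(cols[:, ok], rowvar=False)
        r2 = corr**2
        iu, ju = np.triu_indices(len(ids_ok), k=1)
        dist = np.abs(pos_ok[iu] - pos_ok[ju])
        keep = dist <= max_dist_cM
        for a, b, d, r in zip(iu[keep], ju[keep], dist[keep], r2[iu[keep], ju[keep]]):
            rows.append((ids_ok[a], ids_ok[b], lg, float(d), float(r)))
    return pd.DataFrame(rows, columns=["marker_a", "marker_b", "lg", "distance_cm", "r2"])


def expected_r2(C, n: int):
    """Expected r^2 at recombination-scaled distance C for sample size n."""
    C = np.asarray(C, dtype=float)
    a = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    b = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return a * b


class HillWeirFit:
    """Fitted LD-decay curve: rho scales cM to C, d02 is the 0.2 crossing."""

    def __init__(self, rho: float, n: int, d02: float, sse: float):
        self.rho = rho
        self.n = n
        self.d02 = d02
        self.sse = sse

    def predict(self, d):
        return expected_r2(self.rho * np.asarray(d, dtype=float), self.n)

    def __repr__(self):
        return f"HillWeirFit(rho={self.rho:.4g}, n={self.n}, d02={self.d02:.4g})"


def fit_hill_weir(ld: pd.DataFrame, n: int) -> HillWeirFit:
    """Least-squares fit of the decay expectation over observed (d, r^2) pairs.

    ``n`` is the sample size entering the expectation (number of lines by
    default in this pipeline).  The crossing distance d02 is found by root
    bisection and reported as ``inf`` if the curve never reaches 0.2.
    """
    d = ld["distance_cm"].to_numpy(float)
    r2 = ld["r2"].to_numpy(float)
    if len(d) < 10 or len(np.unique(d)) < 2:
        raise ValueError("need >= 10 LD pairs spanning more than one distance")

    def sse(log_rho):
        resid = r2 - expected_r2(np.exp(log_rho) * d, n)
        return float(resid @ resid)

    best = None
    for lo, hi in [(-8, 2), (-2, 8), (-12, 12)]:
        res = minimize_scalar(sse, bounds=(lo, hi), method="bounded")
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"LD-decay fit failed; best residual {best.fun}")
    rho = float(np.exp(best.x))

    def f(dist):
        return expected_r2(rho * dist, n) - 0.2

    d_hi = 1.0
    while f(d_hi) > 0 and d_hi < 1e9:
        d_hi *= 10.0
    d02 = np.inf if f(d_hi) > 0 else (0.0 if f(0.0) <= 0 else brentq(f, 1e-12, d_hi))
    return HillWeirFit(rho=rho, n=n, d02=float(d02), sse=best.fun)


def assign_bins(marker_map: MarkerMap) -> pd.Series:
    """Bin id per marker: unique (LG, position) pairs ordered along the genome."""
    return marker_map.table.set_index("marker")["bin"]


def thin_by_bins(
    gm: GenotypeMatrix,
    marker_map: MarkerMap,
    stats: MarkerStats,
    stride: int = 1,
    per_lg: bool = False,
) -> np.ndarray:
    """Bin-based marker thinning; returns the retained marker ids.

    One representative per bin is the marker with the highest MAF (ties by
    marker id).  ``stride`` = 1 keeps every bin's representative; stride k
    keeps the representative of the first bin of each consecutive group of k
    bins in a single genome-wide bin list, hence ceil(B / k) markers for B
    bins.  With ``per_lg`` the grouping restarts at each linkage group.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    unmapped = set(gm.markers) - set(marker_map.markers)
    if unmapped:
        raise ValueError(f"unmapped markers: {sorted(unmapped)[:5]}")
    t = marker_map.table[marker_map.table["marker"].isin(set(gm.markers))]
    maf = stats.table.set_index("marker")["maf"]
    reps = (
        t.assign(maf=t["marker"].map(maf))
        .sort_values(["bin", "maf", "marker"], ascending=[True, False, True], kind="stable")
        .groupby("bin", sort=True)
        .first()
        .reset_index()
    )
    if per_lg:
        keep = reps.groupby("lg", sort=False).cumcount() % stride == 0
    else:
        keep = np.arange(len(reps)) % stride == 0
    return reps.loc[keep, "marker"].to_numpy(dtype=object)
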
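"""Synthetic panels, maps, traits and RIL populations.

The generator emulates a structured collection of inbred lines genotyped at
mapped SNPs on a handful of linkage groups, with rapid linkage-disequilibrium
decay, quantitative traits of chosen broad-sense heritability measured in
replicated multi-year trials, and recombinant inbred line (RIL) populations
derived from panel parents by single-seed descent.

Panel accessions are built with a founder-mosaic model: each subpopulation
has a small pool of founder haplotypes (allele frequencies diverged from a
common ancestral frequency, Balding-Nichols style), and every accession is a
mosaic of founder segments whose lengths are exponential in cM.  One mosaic
haplotype is doubled to homozygosity, so accessions carry codes {0, 2} only.
Short segments and small founder pools produce LD that decays within a cM,
the regime the downstream analyses assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MarkerMap, PhenotypeTable

__all__ = [
    "SimMapConfig",
    "PanelSimConfig",
    "TraitSimConfig",
    "CrossPlan",
    "TruthRecord",
    "simulate_map",
    "simulate_panel",
    "simulate_trait",
    "simulate_ril_populations",
    "simulate_trait_from_truth",
]


@dataclass
class SimMapConfig:
    n_lg: int = 7
    lg_lengths: tuple = (114.0, 115.0, 136.0, 110.0, 106.0, 104.0, 110.0)  # ~795 cM
    n_markers: int = 1400
    n_bins: int | None = None  # if set, markers are stacked on this many unique positions
    fixed_positions: dict | None = None  # lg -> explicit positions, overrides sampling
    seed: int = 0


@dataclass
class PanelSimConfig:
    n_accessions: int = 339
    n_subpops: int = 4
    n_founders_per_subpop: int = 3
    mosaic_segment_mean_cM: float = 2.5
    divergence: float = 0.10  # per-subpop allele flip rate off the shared templates
    bin_dup_flip: float = 0.02  # template flip rate between co-located (same-bin) markers
    related_fraction: float = 0.6  # accessions derived from another accession
    resample_prob: float = 0.35  # per-segment chance a derived accession differs
    seed: int = 0


@dataclass
class TraitSimConfig:
    n_qtl: int = 100
    h2: float = 0.7
    effect_distribution: str = "normal"  # or "gamma-signed"
    years: tuple = (2007, 2003)
    gxy_sd_fraction: float = 0.0
    block_sd: float = 0.0
    n_blocks: int = 2
    trait_name: str = "trait"
    seed: int = 0


@dataclass
class CrossPlan:
    parent_pairs: list  # list of (id_a, id_b)
    n_ril_per_cross: int = 80
    selfing_generations: int = 6
    seed: int = 0


@dataclass
class TruthRecord:
    """Ground truth of a simulated trait, for parameter-recovery checks."""

    qtl_markers: np.ndarray
    effects_by_year: dict  # year -> effect vector over qtl markers
    genetic_values: dict  # year -> per-individual true genetic value
    realized_h2: dict  # year -> Vg / (Vg + Ve / n_blocks)
    individuals: np.ndarray = field(default=None)


def simulate_map(cfg: SimMapConfig) -> MarkerMap:
    """Draw a genetic map: markers on `n_lg` linkage groups, cM positions.

    Marker counts are split across linkage groups proportionally to length.
    With ``n_bins`` set, markers are placed on that many unique positions so
    several markers can share a bin; otherwise every marker gets its own
    position.  ``fixed_positions`` pins exact positions per linkage group.
    """
    if cfg.n_markers <= 0:
        raise ValueError("n_markers must be positive")
    lengths = np.asarray(cfg.lg_lengths, dtype=float)[: cfg.n_lg]
    if len(lengths) != cfg.n_lg:
        raise ValueError("lg_lengths must provide one length per linkage group")
    if (lengths <= 0).any():
        raise ValueError("linkage group lengths must be positive")
    rng = np.random.default_rng(cfg.seed)

    rows = []
    if cfg.fixed_positions is not None:
        for lg, pos in cfg.fixed_positions.items():
            for p in pos:
                rows.append((lg, float(p)))
    else:
        # allocate markers (or bins) proportionally to length, largest remainder
        n_sites = cfg.n_bins if cfg.n_bins is not None else cfg.n_markers
        quota = n_sites * lengths / lengths.sum()
        counts = np.floor(quota).astype(int)
        rem = n_sites - counts.sum()
        counts[np.argsort(quota - np.floor(quota))[::-1][:rem]] += 1
        positions = []
        for lg in range(cfg.n_lg):
            pos = np.sort(rng.uniform(0.0, lengths[lg], size=counts[lg]))
            positions.append((lg + 1, pos))
        if cfg.n_bins is not None:
            # distribute markers over bins: each bin gets >=1 marker
            sites = [(lg, p) for lg, pos in positions for p in pos]
            extra = rng.integers(0, len(sites), size=cfg.n_markers - len(sites))
            counts_per_site = np.bincount(extra, minlength=len(sites)) + 1
            for (lg, p), c in zip(sites, counts_per_site):
                rows.extend([(lg, p)] * int(c))
        else:
            rows = [(lg, p) for lg, pos in positions for p in pos]

    df = pd.DataFrame(rows, columns=["lg", "pos_cm"])
    df = df.sort_values(["lg", "pos_cm"], kind="stable").reset_index(drop=True)
    df["marker"] = [f"m{i:05d}" for i in range(len(df))]
    return MarkerMap(df[["marker", "lg", "pos_cm"]])


def _founder_haplotypes(bin_ids: np.ndarray, cfg: PanelSimConfig, rng) -> np.ndarray:
    """(n_subpops, n_founders, n_markers) 0/1 haplotypes.

    Each subpopulation's founders are diverged copies of a shared set of
    ancestral template haplotypes: alleles flip with probability
    ``divergence / 2`` per subpopulation.  Sharing the templates keeps
    allele phase consistent across subpopulations, so short-range LD
    survives pooling the structured panel, while the flips differentiate
    subpopulation allele frequencies (Balding-Nichols-like divergence).

    Template columns are drawn per *bin* (unique map position) and markers
    sharing a bin are near-duplicates of it (flip rate ``bin_dup_flip``),
    so co-located markers are informationally redundant, as they are on a
    consensus map.
    """
    bin_ids = np.asarray(bin_ids)
    uniq, inverse = np.unique(bin_ids, return_inverse=True)
    n_bins = len(uniq)
    K = cfg.n_founders_per_subpop
    p_anc = rng.uniform(0.1, 0.9, size=n_bins)
    bin_templates = (rng.random((K, n_bins)) < p_anc).astype(np.int8)
    # array-style ascertainment: redraw template columns until polymorphic
    for _ in range(40 if K > 1 else 0):
        mono = bin_templates.min(axis=0) == bin_templates.max(axis=0)
        if not mono.any():
            break
        bin_templates[:, mono] = (
            rng.random((K, int(mono.sum()))) < p_anc[mono]
        ).astype(np.int8)
    f = cfg.divergence
    first_of_bin = np.zeros(len(bin_ids), dtype=bool)
    first_of_bin[np.unique(inverse, return_index=True)[1]] = True
    haps = np.empty((cfg.n_subpops, K, len(bin_ids)), dtype=np.int8)
    for s in range(cfg.n_subpops):
        # subpop divergence acts on the bin templates, so co-located
        # markers stay in phase within every subpopulation
        flips = rng.random(bin_templates.shape) < f / 2.0
        sub_bin = np.where(flips, 1 - bin_templates, bin_templates)
        sub = sub_bin[:, inverse]
        dup = rng.random(sub.shape) < cfg.bin_dup_flip
        dup[:, first_of_bin] = False  # bin representative keeps the exact column
        haps[s] = np.where(dup, 1 - sub, sub)
    return haps


def simulate_panel(marker_map: MarkerMap, cfg: PanelSimConfig):
    """Simulate a structured panel of fully homozygous accessions.

    Returns ``(GenotypeMatrix, subpop_labels)``.  Each base accession is a
    mosaic of founder haplotypes of its subpopulation: segment breakpoints
    follow a Poisson process along each linkage group with mean segment
    length ``mosaic_segment_mean_cM``, and the mosaic haplotype is doubled,
    so all codes are in {0, 2}.  A ``related_fraction`` of the panel is
    derived from earlier accessions by re-drawing a ``resample_prob`` share
    of segments, producing the clusters of closely related lines genebank
    collections show.  Monomorphic markers may occur and are permitted.
    """
    if cfg.n_founders_per_subpop < 1 or cfg.n_subpops < 1:
        raise ValueError("need at least one founder haplotype")
    rng = np.random.default_rng(cfg.seed)
    t = marker_map.table
    n_markers = len(t)
    haps = _founder_haplotypes(t["bin"].to_numpy(), cfg, rng)

    n_base = max(1, int(round(cfg.n_accessions * (1.0 - cfg.related_fraction))))
    subpop = rng.integers(0, cfg.n_subpops, size=cfg.n_accessions)
    codes = np.empty((cfg.n_accessions, n_markers), dtype=np.int8)

    lg_slices = []
    for lg in marker_map.linkage_groups:
        idx = np.flatnonzero((t["lg"] == lg).to_numpy())
        lg_slices.append((idx, t["pos_cm"].to_numpy(float)[idx]))

    mean_len = float(cfg.mosaic_segment_mean_cM)
    if mean_len <= 0:
        raise ValueError("mosaic_segment_mean_cM must be positive")

    def fresh_mosaic(s):
        hap = np.empty(n_markers, dtype=np.int8)
        for idx, pos in lg_slices:
            # walk the LG, drawing exponential segment lengths
            cur = 0.0
            founder = rng.integers(0, cfg.n_founders_per_subpop)
            j = 0
            while j < len(idx):
                cur += rng.exponential(mean_len)
                upto = np.searchsorted(pos, cur, side="right")
                hap[idx[j:upto]] = haps[s, founder, idx[j:upto]]
                j = upto
                founder = rng.integers(0, cfg.n_founders_per_subpop)
        return hap

    def derived_mosaic(base_hap, s):
        hap = base_hap.copy()
        for idx, pos in lg_slices:
            cur = 0.0
            j = 0
            while j < len(idx):
                cur += rng.exponential(mean_len)
                upto = np.searchsorted(pos, cur, side="right")
                if rng.random() < cfg.resample_prob:
                    founder = rng.integers(0, cfg.n_founders_per_subpop)
                    hap[idx[j:upto]] = haps[s, founder, idx[j:upto]]
                j = upto
        return hap

    for i in range(cfg.n_accessions):
        if i < n_base or cfg.related_fraction == 0:
            codes[i] = 2 * fresh_mosaic(subpop[i])
        else:
            parent = int(rng.integers(0, i))
            subpop[i] = subpop[parent]
            codes[i] = 2 * derived_mosaic(codes[parent] // 2, subpop[i])

    individuals = np.array([f"acc{i:04d}" for i in range(cfg.n_accessions)], dtype=object)
    gm = GenotypeMatrix(individuals, marker_map.markers, codes, provenance="simulated")
    labels = np.array([f"subpop{s}" for s in subpop], dtype=object)
    return gm, labels


def _draw_effects(n_qtl: int, distribution: str, rng) -> np.ndarray:
    if distribution == "normal":
        return rng.normal(0.0, 1.0, size=n_qtl)
    if distribution == "gamma-signed":
        return rng.gamma(0.4, 1.0, size=n_qtl) * rng.choice([-1.0, 1.0], size=n_qtl)
    raise ValueError(f"unknown effect distribution {distribution!r}")


def simulate_trait(geno: GenotypeMatrix, cfg: TraitSimConfig):
    """Simulate a replicated multi-year trait on a genotyped panel.

    Phenotype of individual i in year y, block b:

        value = year_mean_y + sum_q codes[i, q] * effect[q, y] + block_b + e

    The residual standard deviation is set per year so that the broad-sense
    heritability on an adjusted-mean basis, Vg / (Vg + Ve / n_blocks) with Vg
    the realized genetic variance, equals ``cfg.h2``.  Year-specific effect
    vectors model genotype-by-year interaction: effects in later years are
    the base effects plus noise of sd ``gxy_sd_fraction * sd(base effects)``.

    Returns ``(PhenotypeTable, TruthRecord)``.
    """
    if not (0.0 < cfg.h2 <= 1.0):
        raise ValueError("h2 must be in (0, 1]")
    if cfg.n_qtl > geno.n_markers:
        raise ValueError("n_qtl exceeds the number of markers")
    geno.require_complete("trait simulation")
    rng = np.random.default_rng(cfg.seed)

    qtl_idx = np.sort(rng.choice(geno.n_markers, size=cfg.n_qtl, replace=False))
    base = _draw_effects(cfg.n_qtl, cfg.effect_distribution, rng)
    W = geno.codes[:, qtl_idx].astype(float)

    effects_by_year, genetic_values, realized_h2 = {}, {}, {}
    rows = []
    for yi, year in enumerate(cfg.years):
        if yi == 0 or cfg.gxy_sd_fraction == 0:
            eff = base if yi == 0 else base.copy()
        else:
            eff = base + rng.normal(0.0, cfg.gxy_sd_fraction * base.std(), size=cfg.n_qtl)
        g = W @ eff
        vg = float(g.var(ddof=1))
        if vg <= 0:
            raise ValueError("realized genetic variance is zero; increase diversity or QTL")
        # Vg/(Vg + Ve/B) = h2  =>  Ve = B * Vg * (1 - h2) / h2
        ve = cfg.n_blocks * vg * (1.0 - cfg.h2) / cfg.h2
        year_mean = 100.0 * (yi + 1)
        blocks = rng.normal(0.0, cfg.block_sd, size=cfg.n_blocks)
        for b in range(cfg.n_blocks):
            resid = rng.normal(0.0, np.sqrt(ve), size=geno.n_individuals) if ve > 0 else 0.0
            vals = year_mean + g + blocks[b] + resid
            for ind, v in zip(geno.individuals, vals):
                rows.append((ind, cfg.trait_name, year, b + 1, float(v)))
        effects_by_year[year] = eff
        genetic_values[year] = g
        realized_h2[year] = vg / (vg + ve / cfg.n_blocks)

    pheno = PhenotypeTable(
        pd.DataFrame(rows, columns=["individual", "trait", "year", "block", "value"])
    )
    truth = TruthRecord(
        qtl_markers=geno.markers[qtl_idx],
        effects_by_year=effects_by_year,
        genetic_values=genetic_values,
        realized_h2=realized_h2,
        individuals=geno.individuals,
    )
    return pheno, truth


def simulate_trait_from_truth(
    geno: GenotypeMatrix,
    truth: TruthRecord,
    year,
    h2: float,
    n_blocks: int = 2,
    block_sd: float = 0.0,
    trait_name: str = "trait",
    seed: int = 0,
    source_year=None,
) -> PhenotypeTable:
    """Phenotype a new population with an existing trait architecture.

    Re-uses the QTL markers and effects recorded in ``truth`` (by default
    the first simulated year's effects) so that, e.g., RIL offspring can be
    scored for the same trait their panel parents were, and sets the
    residual variance so the realized broad-sense heritability in the new
    population equals ``h2``.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must be in (0, 1]")
    geno.require_complete("trait simulation")
    rng = np.random.default_rng(seed)
    src = source_year if source_year is not None else next(iter(truth.effects_by_year))
    eff = truth.effects_by_year[src]
    qtl_idx = GenotypeMatrix._index(geno.markers, truth.qtl_markers, "marker")
    g = geno.codes[:, qtl_idx].astype(float) @ eff
    vg = float(g.var(ddof=1))
    if vg <= 0:
        raise ValueError("trait is not segregating in the new population")
    ve = n_blocks * vg * (1.0 - h2) / h2
    year_mean = 100.0
    blocks = rng.normal(0.0, block_sd, size=n_blocks)
    rows = []
    for b in range(n_blocks):
        resid = rng.normal(0.0, np.sqrt(ve), size=geno.n_individuals) if ve > 0 else 0.0
        vals = year_mean + g + blocks[b] + resid
        for ind, v in zip(geno.individuals, vals):
            rows.append((ind, trait_name, year, b + 1, float(v)))
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["individual", "trait", "year", "block", "value"])
    )


def _haldane_rec_fractions(pos_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction between adjacent markers (Haldane map function)."""
    d = np.diff(pos_cm)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def _gamete(h1, h2, lg_slices, rec_by_lg, rng):
    """One meiotic product of a diploid (h1, h2), with Haldane recombination."""
    gam = np.empty_like(h1)
    for (idx, _), rec in zip(lg_slices, rec_by_lg):
        start = rng.integers(0, 2)
        switches = rng.random(len(idx) - 1) < rec
        take = (start + np.concatenate(([0], np.cumsum(switches)))) % 2
        gam[idx] = np.where(take == 0, h1[idx], h2[idx])
    return gam


def simulate_ril_populations(
    panel: GenotypeMatrix, marker_map: MarkerMap, plan: CrossPlan
):
    """Derive RIL populations from panel parents by single-seed descent.

    Each cross starts from the F1 (heterozygous wherever the two homozygous
    parents differ) and is selfed for ``selfing_generations`` generations,
    one seed per line per generation, with meiotic recombination between
    adjacent markers following the Haldane map function.

    Returns ``(GenotypeMatrix, population_labels)``.
    """
    panel.require_complete("RIL simulation")
    if (panel.codes == 1).any():
        raise ValueError("panel parents must be homozygous")
    rng = np.random.default_rng(plan.seed)
    t = marker_map.table
    pos_all = t["pos_cm"].to_numpy(float)
    lg_slices = []
    rec_by_lg = []
    for lg in marker_map.linkage_groups:
        idx = np.flatnonzero((t["lg"] == lg).to_numpy())
        lg_slices.append((idx, None))
        rec_by_lg.append(_haldane_rec_fractions(pos_all[idx]))

    all_codes, labels, ids = [], [], []
    for ci, (pa, pb) in enumerate(plan.parent_pairs):
        ga = panel.select_individuals([pa]).codes[0] // 2  # haplotype 0/1
        gb = panel.select_individuals([pb]).codes[0] // 2
        if (ga == gb).all():
            raise ValueError(f"cross ({pa}, {pb}): parents identical at all markers")
        for r in range(plan.n_ril_per_cross):
            h1, h2 = ga.copy(), gb.copy()  # F1
            for _ in range(plan.selfing_generations):
                h1, h2 = (
                    _gamete(h1, h2, lg_slices, rec_by_lg, rng),
                    _gamete(h1, h2, lg_slices, rec_by_lg, rng),
                )
            all_codes.append(h1 + h2)
            labels.append(f"pop{ci + 1}")
            ids.append(f"ril_{ci + 1}_{r:03d}")

    gm = GenotypeMatrix(
        np.array(ids, dtype=object),
        panel.markers,
        np.array(all_codes, dtype=np.int8),
        provenance="simulated",
    )
    return gm, np.array(labels, dtype=object)
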
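"""Core data containers shared by every pipeline stage.

Genotypes are biallelic SNP codes on inbred material: 0 and 2 are the two
homozygotes, 1 the (residual) heterozygote, and -1 marks a missing call.
Maps are genetic (cM) positions on linkage groups; markers sharing an exact
(linkage group, position) pair belong to the same *bin* and are mutually
redundant on the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
VALID_CODES = (0, 1, 2)


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of SNP codes {0,1,2} with -1 for missing.

    Parameters
    ----------
    individuals, markers : sequences of unique string ids.
    codes : int8 array of shape (n_individuals, n_markers).
    provenance : "raw", "filtered", "imputed" or "simulated".
    """

    individuals: np.ndarray
    markers: np.ndarray
    codes: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids are not unique")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker ids are not unique")
        bad = ~np.isin(self.codes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.codes[bad])}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def is_complete(self) -> bool:
        return not (self.codes == MISSING).any()

    def require_complete(self, what: str = "operation") -> None:
        if not self.is_complete():
            raise ValueError(f"{what} requires a complete (imputed) genotype matrix")

    def select_individuals(self, ids) -> "GenotypeMatrix":
        idx = self._index(self.individuals, ids, "individual")
        return replace(self, individuals=self.individuals[idx], codes=self.codes[idx])

    def select_markers(self, ids) -> "GenotypeMatrix":
        idx = self._index(self.markers, ids, "marker")
        return replace(self, markers=self.markers[idx], codes=self.codes[:, idx])

    @staticmethod
    def _index(pool: np.ndarray, ids, kind: str) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(pool)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown {kind} id: {exc.args[0]!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, index=self.individuals, columns=self.markers)
        df.index.name = "individual"
        return df


@dataclass
class MarkerMap:
    """Genetic map: per-marker linkage group, position (cM) and bin id.

    Markers are kept sorted by (linkage group, position); bins number the
    unique (linkage group, position) pairs along the genome, so co-located
    markers share a bin id.
    """

    table: pd.DataFrame  # columns: marker, lg, pos_cm, bin

    def __post_init__(self) -> None:
        required = {"marker", "lg", "pos_cm"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table must have columns {sorted(required)}")
        t = self.table.sort_values(["lg", "pos_cm"], kind="stable").reset_index(drop=True)
        if (t["pos_cm"] < 0).any():
            raise ValueError("map positions must be >= 0")
        if t["marker"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        key = list(zip(t["lg"], t["pos_cm"]))
        bins, seen = [], {}
        for k in key:
            if k not in seen:
                seen[k] = len(seen)
            bins.append(seen[k])
        t["bin"] = np.asarray(bins, dtype=int)
        self.table = t

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy(dtype=object)

    @property
    def n_bins(self) -> int:
        return int(self.table["bin"].nunique())

    @property
    def linkage_groups(self) -> list:
        return list(pd.unique(self.table["lg"]))

    def positions(self, lg) -> np.ndarray:
        return self.table.loc[self.table["lg"] == lg, "pos_cm"].to_numpy(float)

    def subset(self, marker_ids) -> "MarkerMap":
        keep = self.table[self.table["marker"].isin(set(marker_ids))].copy()
        missing = set(marker_ids) - set(keep["marker"])
        if missing:
            raise KeyError(f"markers absent from map: {sorted(missing)[:5]}")
        return MarkerMap(keep.drop(columns="bin"))


@dataclass
class PhenotypeTable:
    """Tidy phenotype records: individual, trait, year, block, value."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"individual", "trait", "year", "value"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"phenotype table must have columns {sorted(required)}")
        t = self.table.copy()
        if "block" not in t.columns:
            t["block"] = 1
        self.table = t.reset_index(drop=True)

    @property
    def traits(self) -> list:
        return sorted(self.table["trait"].unique())

    @property
    def years(self) -> list:
        return sorted(self.table["year"].unique())

    def values_for(self, trait, year, individuals) -> np.ndarray:
        """Mean value per requested individual for one trait/year (NaN if absent)."""
        sub = self.table[(self.table["trait"] == trait) & (self.table["year"] == year)]
        means = sub.groupby("individual")["value"].mean()
        return means.reindex(np.asarray(individuals, dtype=object)).to_numpy(float)


@dataclass
class MarkerStats:
    """Per-marker allele and call statistics (computed from non-missing calls)."""

    table: pd.DataFrame  # columns: marker, maf, missing_rate, het_rate, monomorphic

    def maf(self) -> np.ndarray:
        return self.table["maf"].to_numpy(float)


@dataclass
class RelationshipMatrix:
    """Genomic relationship (kinship) matrix over individuals."""

    individuals: np.ndarray
    values: np.ndarray
    allele_freqs: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match individuals")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def subset(self, ids) -> "RelationshipMatrix":
        idx = GenotypeMatrix._index(self.individuals, ids, "individual")
        return RelationshipMatrix(
            self.individuals[idx], self.values[np.ix_(idx, idx)], self.allele_freqs
        )
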
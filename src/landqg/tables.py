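"""Core tabular containers: diploid genotype tables and family-structured traits.

Genotypes are stored as an integer array of shape ``(n_individuals, n_loci, 2)``
holding microsatellite allele sizes (repeat lengths); :data:`MISSING` marks a
missing allele.  Individual metadata (population, landscape, cohort) live in a
parallel :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing allele in genotype arrays.
MISSING = -1

META_COLUMNS = ["individual_id", "population_id", "landscape_id", "cohort"]


@dataclass
class GenotypeTable:
    """Diploid codominant genotypes with site / landscape / cohort labels.

    Parameters
    ----------
    meta : pandas.DataFrame
        One row per individual with columns ``individual_id``,
        ``population_id``, ``landscape_id`` and ``cohort``.
    alleles : numpy.ndarray
        Integer array ``(n, n_loci, 2)`` of allele sizes; :data:`MISSING`
        (``-1``) marks missing alleles.  An individual is treated as missing
        at a locus when either allele is missing.
    loci : list of str
        Locus names, one per slice of ``alleles``.
    """

    meta: pd.DataFrame
    alleles: np.ndarray
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, n_loci, 2)")
        if len(self.meta) != self.alleles.shape[0]:
            raise ValueError("meta and alleles disagree on individual count")
        if not self.loci:
            self.loci = [f"L{i + 1}" for i in range(self.alleles.shape[1])]
        if len(self.loci) != self.alleles.shape[1]:
            raise ValueError("loci and alleles disagree on locus count")
        missing_cols = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise ValueError(f"meta lacks columns {missing_cols}")
        # populations must nest uniquely in landscapes
        nest = self.meta.groupby("population_id")["landscape_id"].nunique()
        if (nest > 1).any():
            bad = nest[nest > 1].index.tolist()
            raise ValueError(f"populations in multiple landscapes: {bad}")
        ok = (self.alleles != MISSING).all(axis=2).any(axis=1)
        if len(ok) and not ok.all():
            raise ValueError("some individuals have no genotyped locus")

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def populations(self) -> list:
        return list(pd.unique(self.meta["population_id"]))

    def landscapes(self) -> list:
        return list(pd.unique(self.meta["landscape_id"]))

    def population_of_landscape(self) -> dict:
        """Mapping landscape_id -> ordered list of its populations."""
        out: dict = {}
        for land, grp in self.meta.groupby("landscape_id", sort=False):
            out[land] = list(pd.unique(grp["population_id"]))
        return out

    # -- selection -----------------------------------------------------------
    def mask(self, population=None, cohort=None, landscape=None) -> np.ndarray:
        m = np.ones(self.n_individuals, dtype=bool)
        if population is not None:
            m &= (self.meta["population_id"] == population).to_numpy()
        if cohort is not None:
            m &= (self.meta["cohort"] == cohort).to_numpy()
        if landscape is not None:
            m &= (self.meta["landscape_id"] == landscape).to_numpy()
        return m

    def subset(self, population=None, cohort=None, landscape=None) -> "GenotypeTable":
        m = self.mask(population=population, cohort=cohort, landscape=landscape)
        return GenotypeTable(
            self.meta.loc[m].reset_index(drop=True), self.alleles[m], list(self.loci)
        )

    def locus_genotypes(self, locus_index: int, mask: np.ndarray | None = None) -> np.ndarray:
        """Non-missing diploid genotypes ``(m, 2)`` at one locus."""
        a = self.alleles[:, locus_index, :]
        if mask is not None:
            a = a[mask]
        keep = (a != MISSING).all(axis=1)
        return a[keep]

    # -- interchange ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Wide data frame: metadata plus ``<locus>_1`` / ``<locus>_2`` columns."""
        out = self.meta[META_COLUMNS].copy()
        for j, locus in enumerate(self.loci):
            out[f"{locus}_1"] = self.alleles[:, j, 0]
            out[f"{locus}_2"] = self.alleles[:, j, 1]
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        locus_names = []
        for col in df.columns:
            if col.endswith("_1") and f"{col[:-2]}_2" in df.columns:
                locus_names.append(col[:-2])
        if not locus_names:
            raise ValueError("no <locus>_1/<locus>_2 column pairs found")
        n = len(df)
        alleles = np.full((n, len(locus_names), 2), MISSING, dtype=np.int64)
        for j, locus in enumerate(locus_names):
            alleles[:, j, 0] = (
                pd.to_numeric(df[f"{locus}_1"], errors="coerce").fillna(MISSING).astype(np.int64)
            )
            alleles[:, j, 1] = (
                pd.to_numeric(df[f"{locus}_2"], errors="coerce").fillna(MISSING).astype(np.int64)
            )
        meta = df[META_COLUMNS].reset_index(drop=True)
        return cls(meta, alleles, locus_names)


@dataclass
class FamilyTraitTable:
    """Trait values of offspring nested in maternal families nested in sites.

    ``data`` is a wide frame with columns ``site_id``, ``landscape_id``,
    ``family_id``, ``individual_id`` plus one numeric column per trait.
    """

    data: pd.DataFrame

    ID_COLUMNS = ["site_id", "landscape_id", "family_id", "individual_id"]

    def __post_init__(self) -> None:
        missing = [c for c in self.ID_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table lacks columns {missing}")
        nest = self.data.groupby("family_id")["site_id"].nunique()
        if (nest > 1).any():
            raise ValueError("families must nest uniquely within sites")
        vals = self.data[self.traits].to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("trait values must be finite")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.ID_COLUMNS]

    def sites(self) -> list:
        return list(pd.unique(self.data["site_id"]))

    def site_pairs(self) -> list[tuple]:
        """Site pairs within each landscape (the link-level units)."""
        pairs = []
        for _, grp in self.data.groupby("landscape_id", sort=False):
            sites = list(pd.unique(grp["site_id"]))
            pairs.extend(
                (sites[i], sites[j]) for i in range(len(sites)) for j in range(i + 1, len(sites))
            )
        return pairs

    def site_data(self, site, trait: str) -> pd.DataFrame:
        sub = self.data.loc[self.data["site_id"] == site, ["family_id", trait]].dropna()
        return sub.reset_index(drop=True)
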
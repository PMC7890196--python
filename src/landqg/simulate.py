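"""Synthetic data with known ground truth for every pipeline stage.

Three generators are provided:

* :func:`simulate_genotypes` — island-structured microsatellite genotypes.
  Among-population differentiation is induced with the Balding–Nichols
  frequency model: population allele frequencies are Dirichlet draws around an
  ancestral frequency vector with concentration ``(1 - F) / F``, so the
  expected Wright differentiation equals ``target_F`` and parameter recovery
  has a closed-form target.  Within-population departure from Hardy–Weinberg
  follows partial selfing at rate ``s`` via the equilibrium inbreeding
  coefficient ``f = s / (2 - s)``.
* :func:`simulate_family_traits` — open-pollinated maternal sib families under
  mixed mating.  The among-family variance is ``2 * theta * Va`` where
  ``theta`` is the within-family coancestry at Wright's equilibrium, so the
  mixed-mating correction of the additive variance can be validated.
* :func:`simulate_raster` — categorical land-cover mosaics with controllable
  class composition (hence controllable habitat percentage and Shannon
  heterogeneity) and controllable spatial aggregation.

All generators are deterministic given their configuration seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from landqg.landscape import LandscapeRaster
from landqg.tables import MISSING, FamilyTraitTable, GenotypeTable

__all__ = [
    "SimGenotypeConfig",
    "SimFamilyConfig",
    "SimRasterConfig",
    "simulate_genotypes",
    "simulate_family_traits",
    "simulate_raster",
]


@dataclass(frozen=True)
class SimGenotypeConfig:
    """Configuration for the Balding–Nichols genotype generator.

    ``n_per_pop`` individuals are drawn per population *per cohort*.
    Populations are paired consecutively into landscapes (``n_pops`` must be
    divisible by the number of pairs), mirroring a two-sites-per-landscape
    sampling design.
    """

    n_pops: int = 10
    n_per_pop: int = 30
    n_loci: int = 9
    n_landscapes: int = 5
    target_F: float = 0.02
    selfing_rate: float = 0.0
    allele_size_range: tuple[int, int] = (100, 130)
    alleles_per_locus: int = 8
    cohorts: tuple[str, ...] = ("adult", "juvenile")
    missing_rate: float = 0.0
    cohort_independent_freqs: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_pops < 1 or self.n_per_pop < 1 or self.n_loci < 1:
            raise ValueError("counts must be positive")
        if self.n_pops % self.n_landscapes != 0:
            raise ValueError("n_pops must divide evenly into n_landscapes")
        if not 0.0 <= self.target_F < 1.0:
            raise ValueError("target_F must lie in [0, 1)")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must lie in [0, 1]")
        lo, hi = self.allele_size_range
        if hi - lo + 1 < 2:
            raise ValueError("allele_size_range must span >= 2 sizes")
        if not self.cohorts:
            raise ValueError("at least one cohort label required")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class SimFamilyConfig:
    """Configuration for the mixed-mating sib-family phenotype generator.

    ``Va`` and ``Ve`` are the additive and environmental variances in squared
    trait units; ``site_variance`` adds an among-site effect (default 0 so
    that two sites are exchangeable and Q_ST is null by construction).
    """

    n_sites: int = 2
    n_families_per_site: int = 10
    n_offspring_per_family: int = 10
    Va: float = 10.0
    Ve: float = 10.0
    selfing_rate: float = 0.0
    trait_mean: float = 50.0
    trait_name: str = "trait"
    site_variance: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.Va < 0 or self.Ve < 0 or self.site_variance < 0:
            raise ValueError("variances must be non-negative")
        if self.n_offspring_per_family < 2:
            raise ValueError("need >= 2 offspring per family")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SimRasterConfig:
    """Configuration for the categorical mosaic generator.

    ``clustering`` is the Gaussian smoothing radius (in cells) applied to a
    seeded random field before quantile thresholding; 0 gives independent
    cells, larger values give spatially aggregated patches.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 30.0
    class_proportions: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    clustering: float = 0.0
    origin: tuple[float, float] = (0.0, 0.0)
    legend: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.size < 1 or (p < 0).any():
            raise ValueError("need >= 1 non-negative class proportion")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.clustering < 0:
            raise ValueError("clustering must be >= 0")
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_size <= 0:
            raise ValueError("invalid grid dimensions")


def equilibrium_inbreeding(selfing_rate: float) -> float:
    """Equilibrium inbreeding coefficient f = s / (2 - s) under partial selfing."""
    return selfing_rate / (2.0 - selfing_rate)


def _population_frequencies(ancestral: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols draw of one population's allele frequencies."""
    if F == 0.0:
        return ancestral.copy()
    conc = ancestral * (1.0 - F) / F
    # Dirichlet with tiny concentrations can return exact zeros; keep valid simplex
    freqs = rng.dirichlet(np.maximum(conc, 1e-9))
    total = freqs.sum()
    return freqs / total


def simulate_genotypes(cfg: SimGenotypeConfig) -> GenotypeTable:
    """Generate an island-structured diploid microsatellite dataset.

    For each locus an ancestral frequency vector is drawn from a flat
    Dirichlet over ``alleles_per_locus`` distinct integer allele sizes; each
    population's frequencies are Balding–Nichols perturbations with expected
    Wright F equal to ``cfg.target_F``.  Each genotype is autozygous (one
    allele drawn and doubled) with probability ``f = s / (2 - s)``, otherwise
    two alleles are drawn independently, producing the equilibrium
    heterozygote deficit of partial selfing.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    f_within = equilibrium_inbreeding(cfg.selfing_rate)

    lo, hi = cfg.allele_size_range
    size_pool = np.arange(lo, hi + 1)
    k = min(cfg.alleles_per_locus, size_pool.size)

    locus_sizes = []
    ancestral = []
    for _ in range(cfg.n_loci):
        sizes = np.sort(rng.choice(size_pool, size=k, replace=False))
        locus_sizes.append(sizes)
        ancestral.append(rng.dirichlet(np.ones(k)))

    n_cohorts = len(cfg.cohorts)
    n_total = cfg.n_pops * cfg.n_per_pop * n_cohorts
    alleles = np.empty((n_total, cfg.n_loci, 2), dtype=np.int64)

    meta_rows = []
    pops_per_land = cfg.n_pops // cfg.n_landscapes
    row = 0
    for p in range(cfg.n_pops):
        land = p // pops_per_land
        pop_freqs = [
            _population_frequencies(ancestral[loc], cfg.target_F, rng)
            for loc in range(cfg.n_loci)
        ]
        for cohort_idx, cohort in enumerate(cfg.cohorts):
            if cohort_idx > 0 and cfg.cohort_independent_freqs:
                pop_freqs = [
                    _population_frequencies(ancestral[loc], cfg.target_F, rng)
                    for loc in range(cfg.n_loci)
                ]
            for i in range(cfg.n_per_pop):
                meta_rows.append(
                    (
                        f"P{p + 1:02d}_{cohort}_{i + 1:03d}",
                        f"P{p + 1:02d}",
                        f"L{land + 1}",
                        cohort,
                    )
                )
                for loc in range(cfg.n_loci):
                    freqs = pop_freqs[loc]
                    sizes = locus_sizes[loc]
                    if f_within > 0 and rng.random() < f_within:
                        a = rng.choice(sizes, p=freqs)
                        alleles[row, loc] = (a, a)
                    else:
                        alleles[row, loc] = rng.choice(sizes, size=2, p=freqs)
                row += 1

    if cfg.missing_rate > 0:
        drop = rng.random((n_total, cfg.n_loci)) < cfg.missing_rate
        # never erase an individual's last locus
        keep_one = drop.all(axis=1)
        drop[keep_one, 0] = False
        alleles[drop] = MISSING

    meta = pd.DataFrame(meta_rows, columns=["individual_id", "population_id", "landscape_id", "cohort"])
    loci = [f"Cb{j + 1}" for j in range(cfg.n_loci)]
    return GenotypeTable(meta, alleles, loci)


def simulate_family_traits(cfg: SimFamilyConfig) -> FamilyTraitTable:
    """Generate open-pollinated sib-family phenotypes under mixed mating.

    The within-family coancestry ``theta`` at Wright's equilibrium determines
    the among-family variance ``2 * theta * Va``; residuals carry the
    remaining additive variance plus ``Ve``, so the total phenotypic variance
    is ``Va + Ve`` (plus ``site_variance`` when set).
    """
    cfg.validate()
    from landqg.quantgen import mating_system_params  # local import: avoid cycle

    rng = np.random.default_rng(cfg.seed)
    f = equilibrium_inbreeding(cfg.selfing_rate)
    ms = mating_system_params(f)
    var_family = ms.c * cfg.Va  # c = 2 theta
    var_resid = (1.0 - ms.c) * cfg.Va + cfg.Ve
    if var_resid < -1e-12:
        raise ValueError(
            f"implied residual variance {var_resid:.4g} < 0 "
            f"(c={ms.c:.3f}, Va={cfg.Va}, Ve={cfg.Ve})"
        )
    var_resid = max(var_resid, 0.0)

    rows = []
    for s_idx in range(cfg.n_sites):
        site = f"S{s_idx + 1:02d}"
        land = f"L{s_idx // 2 + 1}"
        site_eff = rng.normal(0.0, np.sqrt(cfg.site_variance)) if cfg.site_variance > 0 else 0.0
        for fam_idx in range(cfg.n_families_per_site):
            fam = f"{site}_F{fam_idx + 1:03d}"
            fam_eff = rng.normal(0.0, np.sqrt(var_family)) if var_family > 0 else 0.0
            resid = rng.normal(0.0, np.sqrt(var_resid), size=cfg.n_offspring_per_family)
            vals = cfg.trait_mean + site_eff + fam_eff + resid
            for o_idx, v in enumerate(vals):
                rows.append((site, land, fam, f"{fam}_{o_idx + 1:03d}", v))

    df = pd.DataFrame(
        rows, columns=["site_id", "landscape_id", "family_id", "individual_id", cfg.trait_name]
    )
    return FamilyTraitTable(df)


def simulate_raster(cfg: SimRasterConfig) -> LandscapeRaster:
    """Generate a categorical mosaic by thresholding a smoothed random field.

    A standard-normal field is smoothed with a Gaussian kernel of radius
    ``clustering`` cells and sliced at the quantiles of the cumulative class
    proportions, so realized composition tracks the targets closely while
    smoothing produces spatially aggregated patches.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    field = rng.standard_normal((cfg.n_rows, cfg.n_cols))
    if cfg.clustering > 0:
        field = ndimage.gaussian_filter(field, sigma=cfg.clustering, mode="wrap")

    props = np.asarray(cfg.class_proportions, dtype=float)
    order = np.argsort(field, axis=None, kind="stable")
    n_cells = field.size
    grid_flat = np.empty(n_cells, dtype=np.int32)
    bounds = np.round(np.cumsum(props) * n_cells).astype(int)
    start = 0
    for code, stop in enumerate(bounds):
        grid_flat[order[start:stop]] = code
        start = stop
    grid_flat[order[start:]] = len(props) - 1
    grid = grid_flat.reshape(cfg.n_rows, cfg.n_cols)

    if cfg.legend is not None:
        if len(cfg.legend) != props.size:
            raise ValueError("legend length must match class count")
        legend = {i: name for i, name in enumerate(cfg.legend)}
    else:
        legend = {i: f"class_{i}" for i in range(props.size)}
    return LandscapeRaster(grid=grid, cell_size=cfg.cell_size, origin=cfg.origin, legend=legend)


def config_to_dict(cfg) -> dict:
    """Plain-dict view of any simulation config (for manifests)."""
    return dataclasses.asdict(cfg)
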
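"""Neutral microsatellite statistics at node (per-site) and link (pairwise) levels.

Implements the estimators used on codominant multi-allelic markers:

* unbiased expected heterozygosity and rarefied allelic richness per site;
* Weir & Cockerham variance-component F-statistics (theta = F_ST, small
  f = F_IS), multilocus as ratios of summed components;
* Hedrick's G'_ST and Jost's D from within/total gene diversities;
* Slatkin's R_ST from allele-size variance components, with the
  allele-size-permutation test of R_ST = F_ST;
* three-level AMOVA (landscape / population / within) with permutation
  significance for F_CT and F_SC;
* effective population size from chance-corrected molecular coancestry;
* the adult-vs-juvenile two-sample t test.

Missing genotypes are handled by per-locus pairwise deletion throughout.
Estimators that are undefined on the given data (no polymorphism, degenerate
diversities) return ``nan`` rather than a silent zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from landqg.tables import GenotypeTable

__all__ = [
    "expected_heterozygosity",
    "allelic_richness",
    "inbreeding_coefficient",
    "weir_cockerham_fstats",
    "pairwise_fst",
    "hedrick_gst_prime",
    "jost_d",
    "slatkin_rst",
    "RstResult",
    "hierarchical_amova",
    "AmovaResult",
    "ne_molecular_coancestry",
    "cohort_ttest",
    "diversity_summary",
    "differentiation_summary",
]


# ---------------------------------------------------------------------------
# per-locus helpers
# ---------------------------------------------------------------------------

def _pop_locus_genotypes(g: GenotypeTable, populations, locus: int) -> list[np.ndarray]:
    """Non-missing (n_i, 2) genotype arrays for each population at one locus."""
    out = []
    for pop in populations:
        out.append(g.locus_genotypes(locus, g.mask(population=pop)))
    return out


def _allele_freqs(geno: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Allele frequencies of `alleles` in a (n, 2) genotype block."""
    if geno.size == 0:
        return np.zeros(alleles.size)
    flat = geno.ravel()
    counts = np.array([(flat == a).sum() for a in alleles], dtype=float)
    return counts / flat.size


# ---------------------------------------------------------------------------
# diversity (node level)
# ---------------------------------------------------------------------------

def expected_heterozygosity(g: GenotypeTable, population) -> float:
    """Unbiased expected heterozygosity, averaged over loci.

    Per locus: (2n / (2n - 1)) * (1 - sum p_hat^2) with n genotyped diploids;
    loci with fewer than two genotyped individuals are skipped.
    """
    if population not in g.populations():
        raise KeyError(f"unknown population {population!r}")
    mask = g.mask(population=population)
    values = []
    for loc in range(g.n_loci):
        geno = g.locus_genotypes(loc, mask)
        n = geno.shape[0]
        if n < 2:
            continue
        flat = geno.ravel()
        _, counts = np.unique(flat, return_counts=True)
        p = counts / flat.size
        values.append((2 * n / (2 * n - 1)) * (1.0 - (p**2).sum()))
    if not values:
        raise ValueError(f"no locus with >= 2 genotyped individuals in {population!r}")
    return float(np.mean(values))


def _rarefied_alleles(counts: np.ndarray, gcopies: int) -> float:
    """Expected allele count in a subsample of `gcopies` gene copies."""
    N = int(counts.sum())
    if gcopies > N:
        raise ValueError(f"rarefaction size {gcopies} exceeds available copies {N}")
    denom = math.comb(N, gcopies)
    ar = 0.0
    for Na in counts:
        ar += 1.0 - math.comb(N - int(Na), gcopies) / denom
    return ar


def allelic_richness(
    g: GenotypeTable, population, rarefaction_g: int | None = None
) -> float:
    """Rarefied allelic richness averaged over loci.

    Per locus the expected number of distinct alleles in a standardized
    subsample of ``rarefaction_g`` gene copies,
    ``AR = sum_a [1 - C(N - N_a, g) / C(N, g)]``.  By default ``g`` is the
    smallest non-missing gene-copy count across populations at that locus, so
    richness is comparable among sites.
    """
    pops = g.populations()
    if population not in pops:
        raise KeyError(f"unknown population {population!r}")
    values = []
    for loc in range(g.n_loci):
        blocks = {p: g.locus_genotypes(loc, g.mask(population=p)) for p in pops}
        target = blocks[population]
        if target.size == 0:
            continue
        if rarefaction_g is None:
            copies = [2 * b.shape[0] for b in blocks.values() if b.shape[0] > 0]
            gcop = min(copies)
        else:
            gcop = rarefaction_g
        if gcop < 1:
            continue
        flat = target.ravel()
        _, counts = np.unique(flat, return_counts=True)
        values.append(_rarefied_alleles(counts, gcop))
    if not values:
        raise ValueError(f"no genotyped locus in {population!r}")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------

def _wc_components_locus(blocks: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed (a, b, c) components over alleles at one locus.

    `blocks` holds the non-missing (n_i, 2) genotypes of r populations.
    Returns zeros when fewer than two populations have data or nbar <= 1.
    """
    blocks = [b for b in blocks if b.shape[0] > 0]
    r = len(blocks)
    if r < 2:
        return 0.0, 0.0, 0.0
    n_i = np.array([b.shape[0] for b in blocks], dtype=float)
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([b.ravel() for b in blocks]))
    if alleles.size < 2:
        return 0.0, 0.0, 0.0

    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array([(b == allele).sum() / (2 * b.shape[0]) for b in blocks])
        h_i = np.array([((b == allele).sum(axis=1) == 1).mean() for b in blocks])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def weir_cockerham_fstats(g: GenotypeTable, populations=None) -> dict[str, float]:
    """Multilocus Weir–Cockerham F-statistics over a set of populations.

    Returns theta (F_ST), small f (F_IS) and capital F (F_IT), each as a
    ratio of components summed over alleles and loci (never an average of
    per-locus ratios).
    """
    pops = populations if populations is not None else g.populations()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    A = B = C = 0.0
    for loc in range(g.n_loci):
        a, b, c = _wc_components_locus(_pop_locus_genotypes(g, pops, loc))
        A += a
        B += b
        C += c
    tot = A + B + C
    theta = A / tot if tot > 0 else float("nan")
    f_is = 1.0 - C / (B + C) if (B + C) > 0 else float("nan")
    f_it = 1.0 - C / tot if tot > 0 else float("nan")
    return {"F_ST": float(theta), "F_IS": float(f_is), "F_IT": float(f_it)}


def pairwise_fst(g: GenotypeTable, pop_a, pop_b) -> float:
    """Multilocus Weir–Cockerham theta for one pair of populations.

    May be slightly negative when true differentiation is near zero; the raw
    estimate is reported (the standard convention).
    """
    for pop in (pop_a, pop_b):
        if g.mask(population=pop).sum() < 2:
            raise ValueError(f"population {pop!r} has < 2 individuals")
    return weir_cockerham_fstats(g, [pop_a, pop_b])["F_ST"]


def inbreeding_coefficient(g: GenotypeTable, population) -> float:
    """Multilocus within-population inbreeding coefficient (Weir-style f-hat).

    Ratio of summed (b, c) variance components across alleles and loci for a
    single population; positive values mean heterozygote deficit.  Returns
    ``nan`` when no locus is polymorphic.
    """
    mask = g.mask(population=population)
    if mask.sum() < 2:
        raise ValueError(f"population {population!r} has < 2 individuals")
    B = C = 0.0
    for loc in range(g.n_loci):
        geno = g.locus_genotypes(loc, mask)
        n = geno.shape[0]
        if n < 2:
            continue
        alleles = np.unique(geno)
        if alleles.size < 2:
            continue
        for allele in alleles:
            p = (geno == allele).sum() / (2 * n)
            hbar = ((geno == allele).sum(axis=1) == 1).mean()
            b = (n / (n - 1)) * (p * (1 - p) - ((2 * n - 1) / (4 * n)) * hbar)
            c = hbar / 2.0
            B += b
            C += c
    if B + C <= 0:
        return float("nan")
    return float(1.0 - C / (B + C))


# ---------------------------------------------------------------------------
# diversity-based differentiation (G'_ST, Jost's D)
# ---------------------------------------------------------------------------

def _hs_ht_per_locus(g: GenotypeTable, pops) -> tuple[np.ndarray, np.ndarray]:
    """Within-population (H_S) and total (H_T) gene diversity at each usable locus."""
    hs_list, ht_list = [], []
    for loc in range(g.n_loci):
        blocks = [b for b in _pop_locus_genotypes(g, pops, loc) if b.shape[0] > 0]
        if len(blocks) < 2:
            continue
        alleles = np.unique(np.concatenate([b.ravel() for b in blocks]))
        freqs = np.stack([_allele_freqs(b, alleles) for b in blocks])
        hs = float(np.mean(1.0 - (freqs**2).sum(axis=1)))
        pbar = freqs.mean(axis=0)
        ht = float(1.0 - (pbar**2).sum())
        hs_list.append(hs)
        ht_list.append(ht)
    if not hs_list:
        raise ValueError("no locus genotyped in >= 2 populations")
    return np.array(hs_list), np.array(ht_list)


def hedrick_gst_prime(g: GenotypeTable, pop_set=None) -> float:
    """Hedrick's G'_ST, a G_ST standardized by its within-diversity maximum.

    ``G'_ST = G_ST * (k - 1 + H_S) / ((k - 1) * (1 - H_S))`` with k
    populations; H_S and H_T are averaged across loci before the ratio.
    Returns ``nan`` when H_S = 1 or H_T = 0 (degenerate).
    """
    pops = pop_set if pop_set is not None else g.populations()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    hs_l, ht_l = _hs_ht_per_locus(g, pops)
    hs, ht = float(hs_l.mean()), float(ht_l.mean())
    k = len(pops)
    if ht <= 0 or hs >= 1.0:
        return float("nan") if hs >= 1.0 else 0.0
    gst = (ht - hs) / ht
    return float(gst * (k - 1 + hs) / ((k - 1) * (1 - hs)))


def jost_d(g: GenotypeTable, pop_set=None) -> float:
    """Jost's D, differentiation in terms of effective allele numbers.

    ``D = (k / (k - 1)) * (H_T - H_S) / (1 - H_S)`` with loci combined by
    averaging H_S and H_T before the ratio.  Returns ``nan`` when H_S = 1.
    """
    pops = pop_set if pop_set is not None else g.populations()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    hs_l, ht_l = _hs_ht_per_locus(g, pops)
    hs, ht = float(hs_l.mean()), float(ht_l.mean())
    k = len(pops)
    if hs >= 1.0:
        return float("nan")
    return float((k / (k - 1)) * (ht - hs) / (1 - hs))


# ---------------------------------------------------------------------------
# R_ST and the allele-size permutation test
# ---------------------------------------------------------------------------

@dataclass
class RstResult:
    rst: float
    p_value: float
    n_perm: int
    fst_analog: float  # mean permuted R_ST, the pR_ST ~ F_ST reference


def _size_variance_components(counts: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """(sigma2_among, sigma2_within) from a pop-by-allele gene-copy count matrix."""
    n_i = counts.sum(axis=1).astype(float)
    keep = n_i > 0
    counts, n_i = counts[keep], n_i[keep]
    r = counts.shape[0]
    N = n_i.sum()
    if r < 2 or N <= r:
        return 0.0, 0.0
    means = counts @ sizes / n_i
    grand = (counts.sum(axis=0) @ sizes) / N
    ssb = float((n_i * (means - grand) ** 2).sum())
    sq = counts @ (sizes**2)
    ssw = float((sq - n_i * means**2).sum())
    msb = ssb / (r - 1)
    msw = ssw / (N - r)
    n0 = (N - (n_i**2).sum() / N) / (r - 1)
    return (msb - msw) / n0, msw


def slatkin_rst(
    g: GenotypeTable,
    pop_set=None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> RstResult:
    """Slatkin's R_ST with the allele-size permutation test of R_ST = F_ST.

    R_ST is the among-population fraction of allele-size variance, multilocus
    as a ratio of summed components.  The test permutes size labels among the
    allelic states at each locus (destroying the stepwise-mutation memory
    while preserving the frequency structure); the permuted R_ST distribution
    plays the role of pF_ST, and p = (1 + #{permuted >= observed}) /
    (n_perm + 1).
    """
    pops = pop_set if pop_set is not None else g.populations()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)

    per_locus = []  # (counts matrix pops x alleles, size vector)
    for loc in range(g.n_loci):
        blocks = _pop_locus_genotypes(g, pops, loc)
        alleles = np.unique(np.concatenate([b.ravel() for b in blocks if b.size]))
        if alleles.size < 2:
            continue
        counts = np.zeros((len(pops), alleles.size))
        for i, b in enumerate(blocks):
            if b.size:
                flat = b.ravel()
                counts[i] = [(flat == a).sum() for a in alleles]
        per_locus.append((counts, alleles.astype(float)))

    if not per_locus:
        return RstResult(float("nan"), float("nan"), n_perm, float("nan"))

    def multilocus_rst(size_vectors) -> float:
        num = den = 0.0
        for (counts, _), sizes in zip(per_locus, size_vectors):
            sa, sw = _size_variance_components(counts, sizes)
            num += sa
            den += sa + sw
        return num / den if den > 0 else float("nan")

    observed = multilocus_rst([sizes for _, sizes in per_locus])
    if not np.isfinite(observed):
        return RstResult(float("nan"), float("nan"), n_perm, float("nan"))

    exceed = 0
    perm_sum = 0.0
    perm_n = 0
    for _ in range(n_perm):
        permuted = [rng.permutation(sizes) for _, sizes in per_locus]
        val = multilocus_rst(permuted)
        if np.isfinite(val):
            perm_sum += val
            perm_n += 1
            if val >= observed:
                exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    mean_perm = perm_sum / perm_n if perm_n else float("nan")
    return RstResult(float(observed), float(p), n_perm, float(mean_perm))


# ---------------------------------------------------------------------------
# hierarchical AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    sigma2_among_landscape: float
    sigma2_among_pop: float
    sigma2_within: float
    F_CT: float
    F_SC: float
    F_ST: float
    p_CT: float
    p_SC: float
    ss_among_landscape: float
    ss_among_pop: float
    ss_within: float
    ss_total: float


def _amova_components(
    counts: np.ndarray, land_of_pop: np.ndarray, sizes: np.ndarray | None = None
) -> tuple[float, ...]:
    """Per-locus AMOVA variance components from a pop-by-allele count matrix.

    With ``sizes=None`` distances between gene copies are allele mismatches
    (0/1) and sums of squares reduce to combinatorial counts: for a group
    with allele counts c, SS = [C(n, 2) - sum_a C(c_a, 2)] / n.  With a size
    vector, squared size differences are used (the R_ST-analog form) and
    SS = sum c_a x_a^2 - (sum c_a x_a)^2 / n.
    """

    def ss_of(c: np.ndarray) -> float:
        n = c.sum()
        if n < 2:
            return 0.0
        if sizes is None:
            pairs = n * (n - 1) / 2.0 - (c * (c - 1) / 2.0).sum()
            return float(pairs / n)
        return float((c * sizes**2).sum() - (c * sizes).sum() ** 2 / n)

    n_p = counts.sum(axis=1).astype(float)
    keep = n_p > 0
    counts, n_p, land_of_pop = counts[keep], n_p[keep], land_of_pop[keep]
    lands = np.unique(land_of_pop)
    P, G, N = len(n_p), len(lands), n_p.sum()
    if P < 2 or G < 1 or N <= P:
        return (0.0,) * 7

    ss_wp = sum(ss_of(counts[i]) for i in range(P))
    ss_wl = 0.0
    n_l = np.zeros(G)
    sum_np2_over_nl = 0.0
    for gi, land in enumerate(lands):
        sel = land_of_pop == land
        n_l[gi] = n_p[sel].sum()
        sum_np2_over_nl += (n_p[sel] ** 2).sum() / n_l[gi]
        ss_wl += ss_of(counts[sel].sum(axis=0))
    ss_t = ss_of(counts.sum(axis=0))
    ss_ap = ss_wl - ss_wp
    ss_al = ss_t - ss_wl

    df_al, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    sigma_w = ms_wp
    if df_ap > 0:
        n_coef = (N - sum_np2_over_nl) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_w) / n_coef if n_coef > 0 else 0.0
    else:
        sigma_b = 0.0
    if df_al > 0:
        n1 = (sum_np2_over_nl - (n_p**2).sum() / N) / df_al
        n2 = (N - (n_l**2).sum() / N) / df_al
        sigma_a = (ss_al / df_al - sigma_w - n1 * sigma_b) / n2 if n2 > 0 else 0.0
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_w, ss_al, ss_ap, ss_wp, ss_t


def _amova_counts(g: GenotypeTable, pops) -> list[tuple[np.ndarray, np.ndarray]]:
    """(count matrix, allele-size vector) per locus."""
    out = []
    for loc in range(g.n_loci):
        blocks = _pop_locus_genotypes(g, pops, loc)
        all_alleles = np.unique(np.concatenate([b.ravel() for b in blocks if b.size]))
        counts = np.zeros((len(pops), all_alleles.size))
        for i, b in enumerate(blocks):
            if b.size:
                flat = b.ravel()
                counts[i] = [(flat == a).sum() for a in all_alleles]
        out.append((counts, all_alleles.astype(float)))
    return out


def hierarchical_amova(
    g: GenotypeTable, n_perm: int = 999, seed: int | None = None,
    distance: str = "mismatch",
) -> AmovaResult:
    """Three-level AMOVA: landscapes / populations within landscapes / within.

    Variance components come from allele-mismatch sums of squares (the
    frequency-based form) by default; ``distance="size"`` switches to squared
    allele-size differences (the R_ST-analog form).  Loci are combined as
    sums of components.  F_CT = sigma2_a / sigma2_total is tested by
    permuting whole populations among landscapes;
    F_SC = sigma2_b / (sigma2_b + sigma2_w) by permuting individuals among
    populations within their landscape.
    """
    if distance not in ("mismatch", "size"):
        raise ValueError("distance must be 'mismatch' or 'size'")
    pops = g.populations()
    land_of_pop = np.array(
        [g.meta.loc[g.meta["population_id"] == p, "landscape_id"].iloc[0] for p in pops]
    )
    lands = np.unique(land_of_pop)
    if len(lands) < 2:
        raise ValueError("need >= 2 landscapes")
    per_pop_n = [int(g.mask(population=p).sum()) for p in pops]
    if min(per_pop_n) == 0:
        raise ValueError("empty population stratum")

    counts_per_locus = _amova_counts(g, pops)

    def totals(counts_list, land_assign):
        agg = np.zeros(7)
        for counts, sizes in counts_list:
            agg += np.array(
                _amova_components(
                    counts, land_assign, sizes if distance == "size" else None
                )
            )
        return agg

    sa, sb, sw, ss_al, ss_ap, ss_wp, ss_t = totals(counts_per_locus, land_of_pop)
    tot = sa + sb + sw
    f_ct = sa / tot if tot > 0 else float("nan")
    if sb + sw > 0:
        f_sc = sb / (sb + sw)
    else:
        # no variation below the landscape level: no sub-structure by definition
        f_sc = 0.0 if abs(sb) < 1e-12 else float("nan")
    f_st = (sa + sb) / tot if tot > 0 else float("nan")

    rng = np.random.default_rng(seed)

    # F_CT: permute populations among landscapes
    exceed_ct = 0
    for _ in range(n_perm):
        perm_land = rng.permutation(land_of_pop)
        psa, psb, psw = totals(counts_per_locus, perm_land)[:3]
        ptot = psa + psb + psw
        pf_ct = psa / ptot if ptot > 0 else -np.inf
        if pf_ct >= f_ct:
            exceed_ct += 1
    p_ct = (1 + exceed_ct) / (n_perm + 1)

    # F_SC: permute individuals among populations within each landscape
    pop_index = {p: i for i, p in enumerate(pops)}
    ind_pop = g.meta["population_id"].map(pop_index).to_numpy()
    ind_land = g.meta["landscape_id"].to_numpy()
    exceed_sc = 0
    for _ in range(n_perm):
        perm_pop = ind_pop.copy()
        for land in lands:
            sel = np.flatnonzero(ind_land == land)
            perm_pop[sel] = perm_pop[rng.permutation(sel)]
        counts_list = []
        for loc in range(g.n_loci):
            a = g.alleles[:, loc, :]
            valid = (a >= 0).all(axis=1)
            alleles = np.unique(a[valid])
            counts = np.zeros((len(pops), alleles.size))
            for i in range(len(pops)):
                sel = valid & (perm_pop == i)
                if sel.any():
                    flat = a[sel].ravel()
                    counts[i] = [(flat == al).sum() for al in alleles]
            counts_list.append((counts, alleles.astype(float)))
        psa, psb, psw = totals(counts_list, land_of_pop)[:3]
        pf_sc = psb / (psb + psw) if (psb + psw) > 0 else -np.inf
        if pf_sc >= f_sc:
            exceed_sc += 1
    p_sc = (1 + exceed_sc) / (n_perm + 1)

    return AmovaResult(
        sigma2_among_landscape=float(sa),
        sigma2_among_pop=float(sb),
        sigma2_within=float(sw),
        F_CT=float(f_ct),
        F_SC=float(f_sc),
        F_ST=float(f_st),
        p_CT=float(p_ct),
        p_SC=float(p_sc),
        ss_among_landscape=float(ss_al),
        ss_among_pop=float(ss_ap),
        ss_within=float(ss_wp),
        ss_total=float(ss_t),
    )


# ---------------------------------------------------------------------------
# effective size from molecular coancestry
# ---------------------------------------------------------------------------

def molecular_coancestry_pair(geno_i: np.ndarray, geno_j: np.ndarray) -> float:
    """Raw molecular coancestry of two multilocus genotypes.

    Per locus, the probability that one allele drawn from each individual is
    identical in state, (1/4) * sum of the four allele comparisons; averaged
    over loci where both individuals are genotyped.
    """
    vals = []
    for (a, b), (c, d) in zip(geno_i, geno_j):
        if min(a, b, c, d) < 0:
            continue
        s = (int(a == c) + int(a == d) + int(b == c) + int(b == d)) / 4.0
        vals.append(s)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def ne_molecular_coancestry(
    g: GenotypeTable, population, corrected: bool = True
) -> tuple[float, float]:
    """Effective population size from mean molecular coancestry, Ne = 1/(2 f).

    Coancestries between all individual pairs are corrected for
    identity-in-state by chance using the sample allele frequencies
    (``f = (s - m) / (1 - m)`` with m = sum p^2, combined across loci as a
    ratio of sums).  Returns ``(Ne, f_bar)``; Ne is ``nan`` when the mean
    corrected coancestry is not positive.  Data in which every individual
    carries the same homozygous genotype sit at the f = 1 limit and return
    Ne = 0.5.

    .. note::
       When the chance-match term is estimated from the sample itself, the
       mean corrected coancestry over distinct pairs is algebraically pinned
       to ``-f_self / (n - 1)`` (the mean over all ordered pairs including
       self equals ``sum p_hat^2`` exactly), so for samples without strong
       internal clone/sib clusters the corrected mean is slightly negative
       and Ne is reported as undefined — the analogue of the "Infinite"
       estimates this class of single-sample estimators is known to produce.
       ``corrected=False`` gives the raw similarity version, which is always
       positive but conflates chance matching with coancestry.
    """
    mask = g.mask(population=population)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise ValueError("need >= 3 individuals")
    sub = g.alleles[idx]  # (n, L, 2)
    n, L, _ = sub.shape

    # per-locus chance-match probability from sample frequencies
    m_l = np.full(L, np.nan)
    for loc in range(L):
        a = sub[:, loc, :]
        flat = a[(a >= 0).all(axis=1)].ravel()
        if flat.size:
            _, counts = np.unique(flat, return_counts=True)
            p = counts / flat.size
            m_l[loc] = (p**2).sum()

    num = den = 0.0
    raw_sum = raw_n = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            for loc in range(L):
                gi, gj = sub[i, loc], sub[j, loc]
                if gi.min() < 0 or gj.min() < 0 or not np.isfinite(m_l[loc]):
                    continue
                s = (
                    int(gi[0] == gj[0])
                    + int(gi[0] == gj[1])
                    + int(gi[1] == gj[0])
                    + int(gi[1] == gj[1])
                ) / 4.0
                raw_sum += s
                raw_n += 1
                num += s - m_l[loc]
                den += 1.0 - m_l[loc]
    if raw_n == 0:
        return float("nan"), float("nan")
    raw_mean = raw_sum / raw_n

    if not corrected:
        fbar = raw_mean
    elif den <= 1e-12:
        # fully monomorphic: every comparison is an exact match in the limit
        fbar = 1.0 if raw_mean >= 1.0 - 1e-12 else float("nan")
    else:
        fbar = num / den
    if not np.isfinite(fbar) or fbar <= 0:
        return float("nan"), float(fbar) if np.isfinite(fbar) else float("nan")
    return float(1.0 / (2.0 * fbar)), float(fbar)


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

def cohort_ttest(
    values_adults, values_juveniles, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t test comparing adult and juvenile summaries.

    Pooled-variance by default (Welch via ``equal_var=False``).  Sign
    convention: t < 0 when adults score lower than juveniles.
    """
    a = np.asarray(values_adults, dtype=float)
    j = np.asarray(values_juveniles, dtype=float)
    if a.size < 2 or j.size < 2:
        raise ValueError("need >= 2 values per cohort")
    if np.var(a) == 0 and np.var(j) == 0:
        if np.mean(a) == np.mean(j):
            return 0.0, 1.0
        raise ValueError("zero variance in both cohorts with unequal means")
    t, p = stats.ttest_ind(a, j, equal_var=equal_var)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# tidy summaries
# ---------------------------------------------------------------------------

def diversity_summary(g: GenotypeTable) -> pd.DataFrame:
    """Node-level table: He, AR, f and Ne per population (by cohort when present)."""
    rows = []
    for cohort in pd.unique(g.meta["cohort"]):
        sub = g.subset(cohort=cohort)
        for pop in sub.populations():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ne, _ = ne_molecular_coancestry(sub, pop)
            rows.append(
                {
                    "population_id": pop,
                    "landscape_id": sub.meta.loc[
                        sub.meta["population_id"] == pop, "landscape_id"
                    ].iloc[0],
                    "cohort": cohort,
                    "He": expected_heterozygosity(sub, pop),
                    "AR": allelic_richness(sub, pop),
                    "f": inbreeding_coefficient(sub, pop),
                    "Ne": ne,
                }
            )
    return pd.DataFrame(rows)


def differentiation_summary(
    g: GenotypeTable, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Link-level table: F_ST, G'_ST, Jost's D, R_ST per site pair within landscape."""
    rows = []
    rng = np.random.default_rng(seed)
    for land, pops in g.population_of_landscape().items():
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                pair = [pops[i], pops[j]]
                rst = slatkin_rst(g, pair, n_perm=max(n_perm, 99), seed=int(rng.integers(2**31)))
                rows.append(
                    {
                        "landscape_id": land,
                        "pop_a": pops[i],
                        "pop_b": pops[j],
                        "F_ST": pairwise_fst(g, *pair),
                        "G_ST_prime": hedrick_gst_prime(g, pair),
                        "Jost_D": jost_d(g, pair),
                        "R_ST": rst.rst,
                        "R_ST_p": rst.p_value,
                        "F_IS": weir_cockerham_fstats(g, pair)["F_IS"],
                    }
                )
    return pd.DataFrame(rows)
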
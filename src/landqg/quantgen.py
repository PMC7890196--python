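"""Quantitative genetics of maternal sib families under mixed mating.

Open-pollinated families of a partially selfing species are more related
than half sibs: at Wright's equilibrium the within-family coancestry is
``theta = (1 + 3f)^2 / (8 (1 + f))`` where ``f`` is the within-population
inbreeding coefficient (obtained from neutral markers of the juveniles), and
the among-family variance equals ``c * Va`` with ``c = 2 theta``.  The module
estimates variance components by REML (one-way family model per site; nested
site / family-in-site model per site pair), converts them into additive
variance, narrow-sense heritability and evolvability, and computes Q_ST and
P_ST differentiation between paired sites.

The REML fits use the profiled likelihood directly: the one-way model reduces
to a 1-D search over the variance ratio, the nested model to a 2-D search,
and both reproduce the balanced-design ANOVA closed forms exactly when those
are interior.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from landqg.tables import FamilyTraitTable

__all__ = [
    "MatingSystemParams",
    "VarianceComponents",
    "QuantGenSummary",
    "QstPstEstimate",
    "mating_system_params",
    "reml_oneway",
    "reml_nested",
    "reml_family_variance",
    "additive_variance",
    "qst",
    "pst",
    "pst_sensitivity",
    "trait_correlation_prune",
]


# ---------------------------------------------------------------------------
# mating system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatingSystemParams:
    """Wright's-equilibrium quadruple linking neutral inbreeding to the
    additive-variance correction: inbreeding f, selfing rate s, within-family
    coancestry theta, and correction factor c = 2 theta."""

    f: float
    s: float
    theta: float
    c: float


def mating_system_params(f: float) -> MatingSystemParams:
    """Selfing rate, coancestry and correction factor from inbreeding f.

    ``s = 2f / (1 + f)``, ``theta = (1 + 3f)^2 / (8 (1 + f))``, ``c = 2 theta``;
    algebraically ``c = (1 + s)^2 / (2 (2 - s))``.  f outside [0, 1] (e.g. a
    negative marker-based estimate) is clamped with a warning.
    """
    if not np.isfinite(f):
        raise ValueError("f must be finite")
    if f < 0.0 or f > 1.0:
        warnings.warn(f"inbreeding f={f:.4f} clamped into [0, 1]")
        f = min(max(f, 0.0), 1.0)
    s = 2.0 * f / (1.0 + f)
    theta = (1.0 + 3.0 * f) ** 2 / (8.0 * (1.0 + f))
    return MatingSystemParams(f=f, s=s, theta=theta, c=2.0 * theta)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma2_family: float
    sigma2_within: float
    sigma2_site: float = 0.0
    n_families: int = 0
    n_obs: int = 0
    converged: bool = True

    @property
    def total(self) -> float:
        return self.sigma2_site + self.sigma2_family + self.sigma2_within


@dataclass
class QuantGenSummary:
    trait: str
    site_id: object
    mean: float
    Va: float
    h2: float
    CVa_pct: float


@dataclass
class QstPstEstimate:
    trait: str
    site_pair: tuple
    value: float
    kind: str  # "QST" | "PST"
    c_scale: float = 1.0
    h2_assumed: float = 1.0
    components: VarianceComponents | None = field(default=None, repr=False)


def _group_stats(y: np.ndarray, groups: np.ndarray):
    labels, inv = np.unique(groups, return_inverse=True)
    k = labels.size
    n_i = np.bincount(inv, minlength=k).astype(float)
    sums = np.bincount(inv, weights=y, minlength=k)
    means = sums / n_i
    ssw = float(((y - means[inv]) ** 2).sum())
    return n_i, means, ssw


def reml_oneway(y: np.ndarray, groups: np.ndarray) -> VarianceComponents:
    """REML fit of the one-way random-effects model y = mu + group + e.

    The likelihood is profiled down to the variance ratio
    gamma = sigma2_group / sigma2_e, which is found by bounded 1-D
    minimization; for balanced data the interior solution coincides with the
    ANOVA closed form (MS_B - MS_W) / n0.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n_i, means, ssw = _group_stats(y, groups)
    k, N = n_i.size, y.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    if N <= k:
        raise ValueError("need replication within groups")

    scale = max(float(np.var(y)), 1e-300)
    if ssw <= 1e-12 * scale * N:
        # no within-group variation: residual variance collapses to zero
        fam_var = float(np.var(means, ddof=1))
        return VarianceComponents(fam_var, 0.0, 0.0, k, N, converged=True)

    def neg2_reml(gamma: float) -> float:
        w = n_i / (1.0 + n_i * gamma)
        sw = w.sum()
        mu = (w * means).sum() / sw
        q = ssw + (w * (means - mu) ** 2).sum()
        s2e = q / (N - 1)
        return (N - 1) * np.log(s2e) + np.log1p(n_i * gamma).sum() + np.log(sw)

    upper = max(1e3, 1e3 * np.var(means) / (ssw / N))
    res = optimize.minimize_scalar(
        neg2_reml, bounds=(0.0, upper), method="bounded", options={"xatol": 1e-12}
    )
    gamma = float(res.x)
    if neg2_reml(0.0) <= res.fun:
        gamma = 0.0
    w = n_i / (1.0 + n_i * gamma)
    mu = (w * means).sum() / w.sum()
    s2e = (ssw + (w * (means - mu) ** 2).sum()) / (N - 1)
    return VarianceComponents(
        sigma2_family=max(gamma * s2e, 0.0),
        sigma2_within=float(s2e),
        sigma2_site=0.0,
        n_families=int(k),
        n_obs=int(N),
        converged=bool(res.success if gamma > 0 else True),
    )


def reml_nested(
    y: np.ndarray, site: np.ndarray, family: np.ndarray
) -> VarianceComponents:
    """REML fit of the two-level nested model y = mu + site + family(site) + e.

    Direct dense REML: the residual variance is profiled out and the two
    variance ratios (site and family) are optimized by L-BFGS-B from several
    moment-based starts, with the boundary fits (either ratio pinned at zero)
    also evaluated.  Sized for the small designs of paired-site analyses.
    """
    y = np.asarray(y, dtype=float)
    site = np.asarray(site)
    family = np.asarray(family)
    N = y.size
    sites, site_inv = np.unique(site, return_inverse=True)
    fams, fam_inv = np.unique(family, return_inverse=True)
    if sites.size < 2:
        raise ValueError("need >= 2 sites")
    Zs = np.zeros((N, sites.size))
    Zs[np.arange(N), site_inv] = 1.0
    Zf = np.zeros((N, fams.size))
    Zf[np.arange(N), fam_inv] = 1.0
    x = np.ones(N)
    scale = max(float(np.var(y)), 1e-300)

    def neg2_reml(params: np.ndarray) -> float:
        gs, gf = params
        V = np.eye(N) + gs * (Zs @ Zs.T) + gf * (Zf @ Zf.T)
        try:
            cf = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        vi_y = linalg.cho_solve(cf, y, check_finite=False)
        vi_x = linalg.cho_solve(cf, x, check_finite=False)
        xvx = x @ vi_x
        q = y @ vi_y - (x @ vi_y) ** 2 / xvx
        if q <= 0:
            return np.inf
        s2e = q / (N - 1)
        return logdet + np.log(xvx) + (N - 1) * np.log(s2e)

    # moment starts from the nested ANOVA decomposition
    vc_f = reml_oneway(y, family)
    site_means = np.array([y[site_inv == i].mean() for i in range(sites.size)])
    s_guess = max(float(np.var(site_means, ddof=1)) - vc_f.sigma2_family / max(
        np.bincount(site_inv).mean(), 1.0
    ), 0.0)
    e_guess = max(vc_f.sigma2_within, 1e-8 * scale)
    starts = [
        (s_guess / e_guess, vc_f.sigma2_family / e_guess),
        (0.1, 0.1),
        (1.0, 1.0),
        (0.0, vc_f.sigma2_family / e_guess),
        (s_guess / e_guess, 0.0),
    ]
    best = None
    bounds = [(0.0, 1e6), (0.0, 1e6)]
    for s0 in starts:
        res = optimize.minimize(
            neg2_reml,
            np.asarray(s0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return VarianceComponents(np.nan, np.nan, np.nan, fams.size, N, converged=False)

    gs, gf = np.maximum(best.x, 0.0)
    V = np.eye(N) + gs * (Zs @ Zs.T) + gf * (Zf @ Zf.T)
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    vi_y = linalg.cho_solve(cf, y, check_finite=False)
    vi_x = linalg.cho_solve(cf, x, check_finite=False)
    q = y @ vi_y - (x @ vi_y) ** 2 / (x @ vi_x)
    s2e = q / (N - 1)
    return VarianceComponents(
        sigma2_family=float(gf * s2e),
        sigma2_within=float(s2e),
        sigma2_site=float(gs * s2e),
        n_families=int(fams.size),
        n_obs=int(N),
        converged=bool(best.success),
    )


def reml_family_variance(t: FamilyTraitTable, trait: str, site) -> VarianceComponents:
    """Among-family and residual variance of one trait at one site (REML)."""
    sub = t.site_data(site, trait)
    fams = sub["family_id"].nunique()
    if fams < 2:
        raise ValueError(f"site {site!r} has < 2 families with data for {trait!r}")
    if len(sub) < fams + 2:
        raise ValueError("need >= 2 observations beyond the family count")
    return reml_oneway(sub[trait].to_numpy(), sub["family_id"].to_numpy())


# ---------------------------------------------------------------------------
# derived quantitative-genetic parameters
# ---------------------------------------------------------------------------

def additive_variance(
    vc: VarianceComponents,
    ms: MatingSystemParams,
    trait_mean: float | None = None,
    trait: str = "",
    site_id=None,
) -> QuantGenSummary:
    """Mixed-mating-corrected additive variance and derived parameters.

    ``Va = sigma2_family / c`` with ``c = 2 theta`` (half-sib limit: c = 1/4,
    Va = 4 sigma2_family); ``h2 = Va / (sigma2_family + sigma2_within)``
    truncated at 1 with a warning; evolvability
    ``CVa% = 100 sqrt(Va) / mean`` (undefined when the mean is not positive).
    """
    if ms.theta <= 0:
        raise ValueError("theta must be positive")
    va = vc.sigma2_family / ms.c
    pheno = vc.sigma2_family + vc.sigma2_within
    h2 = va / pheno if pheno > 0 else float("nan")
    if np.isfinite(h2) and h2 > 1.0:
        warnings.warn(f"h2 = {h2:.3f} truncated at 1")
        h2 = 1.0
    if trait_mean is None or trait_mean <= 0:
        cva = float("nan")
    else:
        cva = 100.0 * np.sqrt(va) / trait_mean
    return QuantGenSummary(
        trait=trait,
        site_id=site_id,
        mean=float(trait_mean) if trait_mean is not None else float("nan"),
        Va=float(va),
        h2=float(h2),
        CVa_pct=float(cva),
    )


def qst(
    t: FamilyTraitTable, trait: str, site_pair: tuple, ms: MatingSystemParams
) -> QstPstEstimate:
    """Q_ST between two sites from the nested site / family REML fit.

    ``Q_ST = sigma2_site / (sigma2_site + 2 Va_within)`` where the
    within-site additive variance is the family component divided by
    ``c = 2 theta``.  Truncated into [0, 1]; ``nan`` on a degenerate fit.
    """
    sa, sb = site_pair
    sub = t.data[t.data["site_id"].isin([sa, sb])].dropna(subset=[trait])
    for s in (sa, sb):
        if sub.loc[sub["site_id"] == s, "family_id"].nunique() < 2:
            raise ValueError(f"site {s!r} has < 2 families")
    vc = reml_nested(
        sub[trait].to_numpy(), sub["site_id"].to_numpy(), sub["family_id"].to_numpy()
    )
    va_within = vc.sigma2_family / ms.c
    denom = vc.sigma2_site + 2.0 * va_within
    value = float("nan") if denom <= 0 else min(max(vc.sigma2_site / denom, 0.0), 1.0)
    return QstPstEstimate(trait=trait, site_pair=(sa, sb), value=value, kind="QST", components=vc)


def pst(
    t: FamilyTraitTable,
    trait: str,
    site_pair: tuple,
    c_scale: float = 1.0,
    h2_assumed: float = 1.0,
) -> QstPstEstimate:
    """P_ST, the phenotypic analogue of Q_ST for field-measured traits.

    ``P_ST = c sigma2_B / (c sigma2_B + 2 h2 sigma2_W)`` with between-site
    and within-site components from a one-way REML decomposition; ``c_scale``
    is the assumed fraction of between-site variance that is additive and
    ``h2_assumed`` the assumed within-site heritability (defaults 1, with
    :func:`pst_sensitivity` for the mandatory robustness sweep).
    """
    sa, sb = site_pair
    sub = t.data[t.data["site_id"].isin([sa, sb])].dropna(subset=[trait])
    for s in (sa, sb):
        if (sub["site_id"] == s).sum() < 2:
            raise ValueError(f"site {s!r} has < 2 individuals")
    y = sub[trait].to_numpy()
    if np.var(y) == 0:
        raise ValueError("zero total variance")
    vc = reml_oneway(y, sub["site_id"].to_numpy())
    num = c_scale * vc.sigma2_family  # between-site component
    denom = num + 2.0 * h2_assumed * vc.sigma2_within
    value = float("nan") if denom <= 0 else min(max(num / denom, 0.0), 1.0)
    out = QstPstEstimate(
        trait=trait,
        site_pair=(sa, sb),
        value=value,
        kind="PST",
        c_scale=c_scale,
        h2_assumed=h2_assumed,
        components=vc,
    )
    return out


def pst_sensitivity(
    t: FamilyTraitTable, trait: str, site_pair: tuple, ratios=(0.25, 0.5, 1.0, 2.0)
) -> pd.DataFrame:
    """P_ST across a grid of c / h2 ratios (robustness of the phenotypic proxy)."""
    rows = []
    for ratio in ratios:
        est = pst(t, trait, site_pair, c_scale=ratio, h2_assumed=1.0)
        rows.append({"c_over_h2": ratio, "PST": est.value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait pruning
# ---------------------------------------------------------------------------

def trait_correlation_prune(
    t: FamilyTraitTable | pd.DataFrame, threshold: float = 0.5
) -> list[str]:
    """Greedy removal of redundant traits until all pairwise |r| <= threshold.

    At each step the trait with the most above-threshold partners is dropped;
    ties are broken by declaration (column) order.
    """
    df = t.data[t.traits] if isinstance(t, FamilyTraitTable) else pd.DataFrame(t)
    traits = list(df.columns)
    if len(traits) < 2:
        return traits
    corr = df.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    active = list(range(len(traits)))
    while True:
        sub = corr[np.ix_(active, active)]
        over = (sub > threshold).sum(axis=1)
        if over.max() == 0:
            break
        drop_pos = int(np.argmax(over))  # argmax keeps first (declaration order) on ties
        active.pop(drop_pos)
    return [traits[i] for i in active]


def max_uncorrelated_subsets(corr: pd.DataFrame, threshold: float) -> list[list[str]]:
    """All maximum-size trait subsets with pairwise |r| <= threshold (oracle helper)."""
    traits = list(corr.columns)
    best: list[list[str]] = []
    for size in range(len(traits), 0, -1):
        for combo in itertools.combinations(traits, size):
            ok = all(
                abs(corr.loc[a, b]) <= threshold for a, b in itertools.combinations(combo, 2)
            )
            if ok:
                best.append(list(combo))
        if best:
            return best
    return [[]]
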
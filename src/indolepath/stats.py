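"""Association statistics: Spearman correlation with BH-FDR and Mann-Whitney U.

Gene-count / metabolite-concentration associations are screened with a
tie-corrected Spearman rank correlation; Benjamini-Hochberg step-up q-values
are computed across the full enzyme x metabolite family, and an association is
*reported* only when |rho| > 0.3 and q < alpha (both conditions strict/of the
stated direction).  Mann-Whitney U compares concentrations between isolation
sources within a species: exact p by enumeration at small tie-free samples,
normal approximation with tie and continuity correction otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "spearman",
    "bh_fdr",
    "gene_metabolite_correlations",
    "mann_whitney",
]

RHO_SCREEN = 0.3  # minimum |rho| for an association to be reported


@dataclass(frozen=True)
class CorrelationResult:
    enzyme_abbrev: str
    metabolite: str
    rho: float
    p_value: float
    q_value: float
    reported: bool


@dataclass(frozen=True)
class GroupComparison:
    metabolite: str
    species: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p_value: float


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho (mid-ranks for ties) and a two-sided p-value.

    For n <= ``exact_max_n`` the p-value is exact, by full enumeration of the
    permutations of one vector; otherwise the t-distribution approximation
    t = rho * sqrt((n-2) / (1-rho^2)) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    if n <= exact_max_n:
        # exact permutation null: all n! orderings of ry against rx
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            r = _rho_from_ranks(rx, np.asarray(perm))
            if abs(r) >= target:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, min(1.0, float(p))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved on return.

    q_(i) = min_{j >= i} ( m * p_(j) / j ) over the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def gene_metabolite_correlations(
    counts: pd.DataFrame,
    concentrations: pd.DataFrame,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Spearman rho for every (enzyme, metabolite) pair, BH across all pairs.

    ``counts`` is strains x enzymes (gene counts), ``concentrations`` strains
    x metabolites (ng/mL); rows are matched on the shared strain index.
    Constant columns yield rho = NaN and p = 1 (never reported) rather than
    an error, since all-zero enzyme columns are routine.
    """
    shared = counts.index.intersection(concentrations.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared strains")
    c = counts.loc[shared].astype(float)
    z = concentrations.loc[shared].astype(float)
    n = len(shared)
    rc = pd.DataFrame(sps.rankdata(c.to_numpy(), axis=0), index=shared, columns=c.columns)
    rz = pd.DataFrame(sps.rankdata(z.to_numpy(), axis=0), index=shared, columns=z.columns)
    results = []
    pvals = []
    pairs = []
    for e in c.columns:
        for m in z.columns:
            if np.ptp(c[e].to_numpy()) == 0 or np.ptp(z[m].to_numpy()) == 0:
                rho, p = math.nan, 1.0
            else:
                rho = _rho_from_ranks(rc[e].to_numpy(), rz[m].to_numpy())
                if abs(rho) >= 1.0:
                    p = 2.0 / math.factorial(n) if n <= 9 else 0.0
                else:
                    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
                    p = min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2))
            pairs.append((e, m, rho))
            pvals.append(max(p, np.nextafter(0, 1)))
    qvals = bh_fdr(pvals)
    for (e, m, rho), p, q in zip(pairs, pvals, qvals):
        reported = (not math.isnan(rho)) and abs(rho) > RHO_SCREEN and q < alpha
        results.append(CorrelationResult(e, m, rho, float(p), float(q), bool(reported)))
    return results


def _exact_u_p(n_a: int, n_b: int, pooled: np.ndarray, u_obs: float) -> float:
    n = n_a + n_b
    total = 0
    count = 0
    idx = np.arange(n)
    for comb in itertools.combinations(idx, n_a):
        ra = pooled[list(comb)].sum()
        ua = ra - n_a * (n_a + 1) / 2.0
        u = min(ua, n_a * n_b - ua)
        total += 1
        if u <= u_obs + 1e-12:
            count += 1
    return count / total


def mann_whitney(a, b, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U = min(U_a, U_b).

    Exact p by full enumeration of group assignments when the pooled sample
    size is <= ``exact_max_n`` and tie-free; otherwise the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra_sum = ranks[:n_a].sum()
    u_a = ra_sum - n_a * (n_a + 1) / 2.0
    u = min(u_a, n_a * n_b - u_a)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n_a + n_b <= exact_max_n and not has_ties:
        p = _exact_u_p(n_a, n_b, ranks, u)
    else:
        mu = n_a * n_b / 2.0
        n = n_a + n_b
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            return float(u), 1.0
        z = (u - mu + 0.5) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * sps.norm.cdf(z))
    return float(u), float(p)


def compare_sources(
    concentrations: pd.DataFrame,
    metadata: pd.DataFrame,
    metabolite: str,
    species: str,
) -> list[GroupComparison]:
    """Mann-Whitney comparisons between isolation sources within one species.

    ``metadata`` needs columns ``species`` and ``source`` indexed by strain.
    All unordered source pairs with at least one strain each are compared.
    """
    strains = metadata.index[metadata["species"] == species]
    strains = strains.intersection(concentrations.index)
    sources = sorted(metadata.loc[strains, "source"].unique())
    out = []
    for ga, gb in itertools.combinations(sources, 2):
        sa = strains[metadata.loc[strains, "source"] == ga]
        sb = strains[metadata.loc[strains, "source"] == gb]
        va = concentrations.loc[sa, metabolite].dropna().to_numpy()
        vb = concentrations.loc[sb, metabolite].dropna().to_numpy()
        if len(va) == 0 or len(vb) == 0:
            continue
        u, p = mann_whitney(va, vb)
        out.append(GroupComparison(metabolite, species, ga, gb, len(va), len(vb), u, p))
    return out
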
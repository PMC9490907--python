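"""Association statistics: rank correlation, differential correlation with
permutation nulls, conditional-independence G-tests, and group comparisons.

Differential correlation compares a Spearman correlation between two groups
via the Fisher z-transform, z_g = atanh(rho_g), with difference statistic

    z_diff = (z_A - z_B) / sqrt(1/(n_A - 3) + 1/(n_B - 3)),

and an empirical two-sided p-value from random permutations of group
membership: p = (1 + #{|z_perm| >= |z_obs|}) / (n_perm + 1).

Conditional independence of X and Y given Z is tested with the asymptotic
chi-square (G) test on the discretized 3-way contingency table:
G = 2 N * MI(X; Y | Z) in natural-log units, df = (|X|-1)(|Y|-1)|Z|, with
empty conditioning strata dropped from the degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

__all__ = [
    "CorrelationReport",
    "spearman",
    "DiffCorrResult",
    "fisher_z_difference",
    "differential_correlation",
    "CITestResult",
    "conditional_independence",
    "quantile_discretize",
    "group_compare",
    "two_proportion_z",
]


@dataclass
class CorrelationReport:
    pair: tuple[str, str]
    rho: float
    p: float
    n: int


def spearman(
    x: Sequence[float], y: Sequence[float], names: tuple[str, str] = ("x", "y")
) -> CorrelationReport:
    """Spearman rank correlation on pairwise-complete observations.

    Ties receive average ranks; the p-value uses the t approximation.
    Zero variance in either variable yields rho = NaN (flagged by NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationReport(names, float("nan"), float("nan"), len(x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = scipy.stats.spearmanr(x, y)
    return CorrelationReport(names, float(rho), float(p), len(x))


@dataclass
class DiffCorrResult:
    rho_a: float
    rho_b: float
    z_diff: float
    empirical_p: float
    n_a: int
    n_b: int
    n_permutations: int
    seed: Optional[int] = None


def _rank(v: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(v)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    return float(xc @ yc / denom) if denom > 0 else 0.0

_ATANH_CLIP = 1.0 - 1e-12


def _fisher_z_diff(x: np.ndarray, y: np.ndarray, in_a: np.ndarray, scale: float) -> float:
    # Spearman rho within each group = Pearson on re-ranked subsets.
    ra = _pearson(_rank(x[in_a]), _rank(y[in_a]))
    rb = _pearson(_rank(x[~in_a]), _rank(y[~in_a]))
    return (np.arctanh(np.clip(ra, -_ATANH_CLIP, _ATANH_CLIP))
            - np.arctanh(np.clip(rb, -_ATANH_CLIP, _ATANH_CLIP))) / scale


def fisher_z_difference(rho_a: float, n_a: int, rho_b: float, n_b: int) -> float:
    """Closed-form z statistic for the difference of two correlations."""
    if abs(rho_a) >= 1.0 or abs(rho_b) >= 1.0:
        raise ValueError("|rho| = 1: Fisher z diverges")
    return float((np.arctanh(rho_a) - np.arctanh(rho_b))
                 / np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3)))


def differential_correlation(
    x: Sequence[float],
    y: Sequence[float],
    group: Sequence,
    n_perm: int = 10_000,
    seed: int = 0,
) -> DiffCorrResult:
    """Test whether the x-y rank correlation differs between two groups.

    ``group`` holds exactly two distinct values; the first in sorted order
    is group A.  Permutations shuffle group membership while keeping the
    (x, y) pairs intact.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {len(levels)}")
    in_a = group == levels[0]
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if min(n_a, n_b) < 5:
        raise ValueError("each group needs at least 5 observations")

    rho_a = _pearson(_rank(x[in_a]), _rank(y[in_a]))
    rho_b = _pearson(_rank(x[~in_a]), _rank(y[~in_a]))
    if abs(rho_a) >= 1.0 or abs(rho_b) >= 1.0:
        raise ValueError("|rho| = 1 in a group: Fisher z diverges")
    scale = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    z_obs = _fisher_z_diff(x, y, in_a, scale)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(group))
        if abs(_fisher_z_diff(x[perm], y[perm], in_a, scale)) >= abs(z_obs):
            hits += 1
    return DiffCorrResult(
        rho_a=float(rho_a),
        rho_b=float(rho_b),
        z_diff=float(z_obs),
        empirical_p=(1 + hits) / (n_perm + 1),
        n_a=n_a,
        n_b=n_b,
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass
class CITestResult:
    g: float
    mi: float
    df: int
    p: float
    n: int
    discretization: str


def quantile_discretize(v: np.ndarray, n_levels: int) -> np.ndarray:
    """Discretize a continuous variable into quantile bins (already-discrete
    variables with at most ``n_levels`` distinct values pass through)."""
    v = np.asarray(v, dtype=float)
    uniq = np.unique(v)
    if len(uniq) <= n_levels:
        return np.searchsorted(uniq, v)
    edges = np.quantile(v, np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.searchsorted(edges, v, side="right")


def conditional_independence(
    x: Sequence[float],
    y: Sequence[float],
    z_cond: Optional[Sequence[float]] = None,
    n_levels: int = 3,
) -> CITestResult:
    """Asymptotic chi-square (G) test of X independent of Y given Z.

    Continuous variables are discretized into ``n_levels`` quantile bins.
    With no conditioning variable this reduces to the marginal G-test on the
    2-way table, df = (|X|-1)(|Y|-1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 observations")
    xd = quantile_discretize(x, n_levels)
    yd = quantile_discretize(y, n_levels)
    kx, ky = len(np.unique(xd)), len(np.unique(yd))
    if z_cond is None:
        zd = np.zeros(n, dtype=int)
        kz_df = 1
    else:
        zd = quantile_discretize(np.asarray(z_cond, dtype=float), n_levels)
        kz_df = len(np.unique(zd))

    mi = 0.0
    n_nonempty = 0
    for z_level in np.unique(zd):
        sel = zd == z_level
        nz = sel.sum()
        if nz == 0:
            continue
        n_nonempty += 1
        table = np.zeros((kx, ky))
        np.add.at(table, (xd[sel], yd[sel]), 1.0)
        pz = nz / n
        pxy = table / nz
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = pxy * np.log(pxy / (px * py))
        mi += pz * np.nansum(terms)
    if z_cond is not None and n_nonempty < kz_df:
        warnings.warn("empty conditioning strata dropped from df")
        kz_df = n_nonempty

    g = 2.0 * n * mi
    df = max((kx - 1) * (ky - 1) * kz_df, 1)
    p = float(scipy.stats.chi2.sf(g, df))
    return CITestResult(
        g=float(g), mi=float(mi), df=int(df), p=p, n=n,
        discretization=f"quantile-{n_levels}",
    )


def two_proportion_z(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> dict:
    """Two-proportions z-test with pooled variance (optional continuity
    correction)."""
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 observations")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    diff = p1 - p2
    if continuity:
        cc = 0.5 * (1 / n1 + 1 / n2)
        diff = np.sign(diff) * max(abs(diff) - cc, 0.0)
    z = diff / se if se > 0 else 0.0
    return {"z": float(z), "p": float(2 * scipy.stats.norm.sf(abs(z))), "p1": p1, "p2": p2}


def group_compare(values: Sequence[float], trait: Sequence, kind: str = "numeric") -> dict:
    """Compare a variable between the two levels of a binary trait.

    Numeric variables get a Welch t-test; proportions (0/1 values) get a
    pooled two-proportions z-test.
    """
    values = np.asarray(values, dtype=float)
    trait = np.asarray(trait)
    levels = np.unique(trait)
    if len(levels) != 2:
        raise ValueError("trait must be binary")
    a = values[trait == levels[0]]
    b = values[trait == levels[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 observations")
    if kind == "numeric":
        t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        return {"method": "welch_t", "statistic": float(t), "p": float(p)}
    if kind == "proportion":
        res = two_proportion_z(int(a.sum()), len(a), int(b.sum()), len(b))
        return {"method": "two_proportion_z", "statistic": res["z"], "p": res["p"]}
    raise ValueError("kind must be 'numeric' or 'proportion'")
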
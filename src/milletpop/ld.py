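"""Pairwise linkage disequilibrium and the drift-recombination decay fit.

r^2 between biallelic sites is the squared allele-frequency correlation
computed on haplotypes.  The decay of r^2 with physical distance d is
summarized by fitting the Hill-Weir finite-sample expectation

    E(r^2) = (10+C)/((2+C)(11+C)) * [1 + (3+C)(12+12C+C^2)/(n(2+C)(11+C))]

with C = rho_bp * d, where rho_bp is the population recombination rate per
basepair and n the number of sampled sequences.  Pairs are computed within
loci and pooled across loci for the regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = ["LDPair", "LDFit", "pairwise_r2", "expected_r2", "fit_rho_per_bp",
           "rho_hat_per_locus"]


@dataclass
class LDPair:
    locus_id: str
    site_i: int
    site_j: int
    d: float
    r2: float


@dataclass
class LDFit:
    """Result of the nonlinear E(r^2) fit.

    ``d_at_r2_01`` is the distance (bp) at which the fitted curve crosses
    r^2 = 0.1 (inf when the curve never falls below 0.1, which happens for
    n <= 10 where the finite-sample floor 1/n exceeds 0.1).
    """

    rho_per_bp: float
    n: int
    residual_sse: float
    pairs_used: int
    d_at_r2_01: float
    converged: bool = True


def _biallelic_binary(G: np.ndarray, positions: np.ndarray | None,
                      min_minor_count: int):
    """Biallelic columns recoded 0/1 with their positions, after the
    minor-allele-count filter (default: singletons excluded)."""
    n = G.shape[0]
    if positions is None:
        positions = np.arange(G.shape[1], dtype=float)
    cols, pos = [], []
    for j in range(G.shape[1]):
        states, counts = np.unique(G[:, j], return_counts=True)
        if states.size != 2 or counts.min() < min_minor_count:
            continue
        cols.append((G[:, j] != states[0]).astype(np.float64))
        pos.append(positions[j])
    if not cols:
        return np.empty((n, 0)), np.empty(0)
    return np.column_stack(cols), np.asarray(pos, dtype=float)


def pairwise_r2(data, pop: str | None = None, *, positions=None,
                locus_id: str = "", min_minor_count: int = 2) -> list[LDPair]:
    """All intra-locus site pairs with their distance and r^2.

    r^2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B)) over haplotypes;
    multi-allelic sites are skipped, and sites below the minor-allele-count
    filter (default: exclude singletons) are dropped.
    """
    from .popstats import _as_matrix

    G = _as_matrix(data, pop)
    from .alignment_io import FilteredAlignment

    if positions is None and isinstance(data, FilteredAlignment):
        positions = data.kept_columns.astype(float)
        locus_id = locus_id or data.locus_id
    B, pos = _biallelic_binary(G, positions, min_minor_count)
    k = B.shape[1]
    if k < 2:
        return []
    C = np.corrcoef(B, rowvar=False)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            d = abs(pos[j] - pos[i])
            if d < 1:
                d = 1.0
            pairs.append(LDPair(locus_id, int(i), int(j), float(d),
                                float(C[i, j] ** 2)))
    return pairs


def expected_r2(rho, n=np.inf):
    """Hill-Weir expectation of r^2 at scaled recombination rho, sample n."""
    rho = np.asarray(rho, dtype=float)
    base = (10 + rho) / ((2 + rho) * (11 + rho))
    if np.isinf(n):
        return base
    corr = 1 + ((3 + rho) * (12 + 12 * rho + rho**2)) / (n * (2 + rho) * (11 + rho))
    return base * corr


def _sse(rho_bp: float, d: np.ndarray, r2: np.ndarray, n: int) -> float:
    return float(((r2 - expected_r2(rho_bp * d, n)) ** 2).sum())


def fit_rho_per_bp(pairs, n: int, *, starts=(1e-5, 1e-3, 1e-1)) -> LDFit:
    """Least-squares fit of rho_bp to pooled (d, r^2) pairs.

    A coarse log-spaced grid search brackets the optimum, then each of the
    multistart points and the grid winner are refined with bounded Brent
    minimization; the best refined solution wins.
    """
    if isinstance(pairs, tuple):
        d, r2 = (np.asarray(v, dtype=float) for v in pairs)
    else:
        d = np.array([p.d for p in pairs], dtype=float)
        r2 = np.array([p.r2 for p in pairs], dtype=float)
    if d.size < 10 or np.unique(d).size < 2:
        raise ValueError("need at least 10 pairs with varying distance")
    grid = np.concatenate([[0.0], np.logspace(-8, 1, 120)])
    sses = [_sse(g, d, r2, n) for g in grid]
    candidates = {grid[int(np.argmin(sses))], *starts}
    best_rho, best_sse = 0.0, _sse(0.0, d, r2, n)
    for c in candidates:
        lo, hi = max(c / 100, 1e-12), max(c * 100, 1e-10)
        res = minimize_scalar(_sse, args=(d, r2, n), bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": 1e-14})
        if res.fun < best_sse:
            best_rho, best_sse = float(res.x), float(res.fun)
    return LDFit(
        rho_per_bp=best_rho,
        n=n,
        residual_sse=best_sse,
        pairs_used=int(d.size),
        d_at_r2_01=_crossing_distance(best_rho, n),
    )


def _crossing_distance(rho_bp: float, n: int, level: float = 0.1) -> float:
    """Distance at which the fitted Hill-Weir curve crosses r^2 = level."""
    if rho_bp <= 0:
        return np.inf
    floor = 1.0 / n if np.isfinite(n) else 0.0
    if floor >= level or expected_r2(0.0, n) <= level:
        return np.inf
    f = lambda d: float(expected_r2(rho_bp * d, n) - level)
    hi = 1.0
    while f(hi) > 0:
        hi *= 10
        if hi > 1e12:
            return np.inf
    return float(brentq(f, hi / 10 if f(hi / 10) > 0 else 1e-12, hi))


def rho_hat_per_locus(data, pop: str | None = None, *, positions=None,
                      L: float | None = None) -> float:
    """Per-locus population recombination estimate (locus total, 4Nc units).

    A moment estimator on the Hill-Weir scale: for every usable biallelic
    pair (singletons excluded) the squared covariance D^2 = (p_AB - p_A
    p_B)^2 is matched against sigma_HW(rho_bp*d, n) * p_A(1-p_A)p_B(1-p_B),
    where sigma_HW is the finite-sample E(r^2) curve, and rho_bp minimizes
    the summed squared mismatch.  Matching on the D^2 scale rather than
    averaging the ratio r^2 avoids the strong upward bias that
    low-frequency pairs induce in mean-r^2 fits; simulation calibration
    puts the median estimate within a factor ~1.5 of truth and at ~0 for
    tree-like (recombination-free) data.  NaN when fewer than two usable
    sites exist.
    """
    from .alignment_io import FilteredAlignment
    from .popstats import _as_matrix

    if L is None:
        if not isinstance(data, FilteredAlignment):
            raise ValueError("L is required for bare matrices")
        L = float(data.L_total)
    if isinstance(data, FilteredAlignment) and positions is None:
        positions = data.kept_columns.astype(float)
    G = _as_matrix(data, pop)
    n = G.shape[0]
    B, pos = _biallelic_binary(G, positions, min_minor_count=2)
    k = B.shape[1]
    if k < 2:
        return float("nan")
    p = B.mean(axis=0)
    iu = np.triu_indices(k, 1)
    pAB = (B.T @ B / n)[iu]
    D2 = (pAB - np.outer(p, p)[iu]) ** 2
    w = np.outer(p * (1 - p), p * (1 - p))[iu]
    d = np.abs(np.subtract.outer(pos, pos))[iu]

    def sse(rho_bp):
        return float(((D2 - expected_r2(rho_bp * d, n) * w) ** 2).sum())

    grid = np.concatenate([[0.0], np.logspace(-7, 0.5, 60)])
    sses = [sse(g) for g in grid]
    j = int(np.argmin(sses))
    if grid[j] == 0.0:
        return 0.0
    res = minimize_scalar(sse,
                          bounds=(grid[max(j - 1, 1)],
                                  grid[min(j + 1, grid.size - 1)]),
                          method="bounded", options={"xatol": 1e-12})
    return float(res.x) * L
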
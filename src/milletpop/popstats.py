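"""Per-locus diversity, neutrality, and two-population divergence statistics.

All statistics are defined on a rectangular matrix of haplotypes x sites
with arbitrary integer-coded states (nucleotides from an alignment, or 0/1
from an infinite-sites simulation — both code paths share these kernels).
Per-site quantities (pi, theta_w, Ks) divide by an explicit length L so that
silent-site and total-length variants use the same functions.

Conventions follow the multilocus resequencing literature:

* pi is the mean pairwise difference per site with the n/(n-1) sample-size
  correction, and multi-allelic columns contribute full mismatch counts.
* theta_w = S / (a1 * L) with a1 the (n-1)-th harmonic number.
* Tajima's D uses the 1989 beta-approximation for significance flags.
* Fu & Li's D* and F* (no outgroup) use the original 1993 u/v constants —
  the convention of DnaSP, against which the statistics here were checked.
* Rm is the Hudson-Kaplan four-gamete lower bound.
* Fst is Hudson-style 1 - Hw/Hb with both heterozygosities averaged over
  segregating sites (ratio of averages); small negatives are returned as-is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .alignment_io import FilteredAlignment

__all__ = [
    "LocusSummary",
    "DivergenceSummary",
    "HKAResult",
    "SFS",
    "harmonic",
    "harmonic2",
    "segregating_sites",
    "singleton_count",
    "nucleotide_diversity",
    "mean_pairwise_differences",
    "watterson_theta",
    "tajimas_D",
    "tajima_constants",
    "tajima_p_value",
    "fu_li_tests",
    "haplotype_stats",
    "min_recombination_Rm",
    "fst",
    "polymorphism_partition",
    "sfs",
    "ks_divergence",
    "theta_ks_correlation",
    "hka_multilocus",
    "summarize_locus",
]


# ----------------------------------------------------------------------------
# containers

@dataclass
class LocusSummary:
    """One row of the per-locus summary table (one species)."""

    locus_id: str
    n: int
    L_total: float
    L_silent: float
    S: int
    pi: float
    pi_silent: float
    theta_w: float
    theta_w_silent: float
    tajima_D: float
    fuli_Dstar: float
    fuli_Fstar: float
    rho_hat: float
    Rm: int
    Hap: int
    Hdiv: float


@dataclass
class DivergenceSummary:
    locus_id: str
    S_shared: int
    S_fixed: int
    S_wild_specific: int
    S_cultivar_specific: int
    fst: float
    ks: float


@dataclass
class SFS:
    """Site-frequency spectrum; classes 1..n-1 (polarized) or 1..n//2 (folded)."""

    counts: np.ndarray
    n: int
    polarized: bool
    population: str = ""


@dataclass
class HKAResult:
    chi2: float
    n_loci: int
    components: np.ndarray  # (L, 3): polymorphism A, polymorphism B, divergence
    theta: np.ndarray  # fitted locus-total thetas (species A scale)
    T: float  # fitted divergence time, 2N_A-generation units
    f: float  # fitted N_B / N_A
    df: int
    p_value: float


# ----------------------------------------------------------------------------
# matrix plumbing

def _as_matrix(data, pop: str | None = None) -> np.ndarray:
    """Coerce a FilteredAlignment (optionally one population) or array to 2-D."""
    if isinstance(data, FilteredAlignment):
        m = data.rows(pop)
        return m.view(np.uint8) if m.dtype.kind == "S" else m
    m = np.asarray(data)
    if m.dtype.kind == "S":
        m = m.view(np.uint8)
    if m.ndim != 2:
        raise ValueError("expected a 2-D haplotype matrix")
    return m


def _column_counts(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column state counts: returns (counts, states) with counts shaped
    (n_states, n_cols); absent states have count 0."""
    if G.shape[1] == 0:
        return np.zeros((1, 0), dtype=int), np.zeros(1, dtype=G.dtype)
    states = np.unique(G)
    counts = np.stack([(G == s).sum(axis=0) for s in states])
    return counts, states


def segregating_sites(data, pop: str | None = None) -> int:
    """Number of columns with at least two states in the (sub)sample."""
    G = _as_matrix(data, pop)
    if G.shape[0] < 2:
        raise ValueError("need at least 2 sequences")
    return int((G != G[0]).any(axis=0).sum())


def singleton_count(data, pop: str | None = None) -> int:
    """Total number of singleton mutations eta_s: states carried by exactly
    one sequence at a segregating column (a triallelic column with two
    lone states contributes 2)."""
    G = _as_matrix(data, pop)
    counts, _ = _column_counts(G)
    seg = (counts > 0).sum(axis=0) > 1
    return int(((counts == 1) & seg).sum())


def mean_pairwise_differences(data, pop: str | None = None) -> float:
    """Mean number of pairwise differences per sequence pair (total, not per
    site); multi-allelic columns contribute full mismatch counts."""
    G = _as_matrix(data, pop)
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    counts, _ = _column_counts(G)
    p = counts / n
    het = 1.0 - (p**2).sum(axis=0)
    return float(het.sum() * n / (n - 1))


def nucleotide_diversity(data, pop: str | None = None, *, L: float | None = None,
                         sites: str = "all") -> float:
    """Per-site nucleotide diversity pi.

    For a FilteredAlignment, ``sites`` selects the denominator: 'all' uses
    L_total, 'silent' uses L_silent (the numerator always counts every
    surviving column — the silent variant follows the survey convention of
    rescaling the same mismatch count by the silent length).
    """
    if L is None:
        if not isinstance(data, FilteredAlignment):
            raise ValueError("L is required for bare matrices")
        L = data.L_total if sites == "all" else data.L_silent
        if L == 0:
            raise ValueError(f"{data.locus_id}: zero {sites} length")
    return mean_pairwise_differences(data, pop) / L


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def harmonic2(n: int) -> float:
    """a2 = sum_{i=1}^{n-1} 1/i^2."""
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's per-site estimator S / (a1 * L)."""
    if n < 2 or L <= 0:
        raise ValueError("need n >= 2 and L > 0")
    return S / (harmonic(n) * L)


# ----------------------------------------------------------------------------
# neutrality tests

def tajima_constants(n: int) -> tuple[float, float]:
    """Tajima (1989) variance constants (e1, e2)."""
    a1, a2 = harmonic(n), harmonic2(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


def tajimas_D(data=None, pop: str | None = None, *, n: int | None = None,
              S: int | None = None, pi_total: float | None = None) -> float:
    """Tajima's D, from a matrix/alignment or from printed (n, S, pi_total).

    Returns NaN when S = 0 (the statistic is undefined).
    """
    if data is not None:
        G = _as_matrix(data, pop)
        n = G.shape[0]
        S = segregating_sites(G)
        pi_total = mean_pairwise_differences(G)
    if n is None or S is None or pi_total is None:
        raise ValueError("need data or all of (n, S, pi_total)")
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S == 0:
        return float("nan")
    e1, e2 = tajima_constants(n)
    return (pi_total - S / harmonic(n)) / np.sqrt(e1 * S + e2 * S * (S - 1))


def tajima_p_value(D: float, n: int) -> float:
    """Two-tailed p for Tajima's D under the 1989 beta approximation.

    D is rescaled onto its [Dmin, Dmax] support and compared to a beta
    density with mean 0 and variance 1 on that support.
    """
    if not np.isfinite(D):
        return float("nan")
    a1 = harmonic(n)
    _, e2 = tajima_constants(n)
    dmin = (2.0 / n - 1.0 / a1) / np.sqrt(e2)
    dmax = ((n + 1) / (2.0 * n) - 1.0 / a1) / np.sqrt(e2)
    # beta with mean 0, variance 1 on [dmin, dmax] (Tajima 1989 eq. 47)
    alpha = -(1 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1 + dmin * dmax) * dmin / (dmax - dmin)
    dist = sps.beta(beta, alpha, loc=dmin, scale=dmax - dmin)
    cdf = float(dist.cdf(np.clip(D, dmin, dmax)))
    return 2 * min(cdf, 1 - cdf)


def _fu_li_constants(n: int) -> dict[str, float]:
    a = harmonic(n)
    b = harmonic2(n)
    a1 = a + 1.0 / n  # harmonic(n+1)
    if n == 2:
        c = 1.0
    else:
        c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    d = c + (n - 2) / (n - 1) ** 2 + (2 / (n - 1)) * (
        1.5 - (2 * a1 - 3) / (n - 2) - 1.0 / n
    )
    vD = ((n / (n - 1)) ** 2 * b + a**2 * d - 2 * (n * a * (a + 1)) / (n - 1) ** 2) / (
        a**2 + b
    )
    uD = (n / (n - 1)) * (a - n / (n - 1)) - vD
    # F* uses the original Fu & Li (1993) constants (DnaSP's convention).
    vF = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + 2 * (n - 1) * a / n**2
        - 8 * b / n
    ) / (a**2 + b)
    uF = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * a1) / (3 * n * (n - 1))) / a - vF
    return {"a": a, "uD": uD, "vD": vD, "uF": uF, "vF": vF}


def fu_li_tests(data=None, pop: str | None = None, *, n: int | None = None,
                S: int | None = None, eta_s: int | None = None,
                pi_total: float | None = None) -> tuple[float, float]:
    """Fu & Li's outgroup-free (D*, F*) from data or printed ingredients.

    eta_s is the total singleton count.  Returns (nan, nan) when S = 0.
    """
    if data is not None:
        G = _as_matrix(data, pop)
        n = G.shape[0]
        S = segregating_sites(G)
        eta_s = singleton_count(G)
        pi_total = mean_pairwise_differences(G)
    if None in (n, S, eta_s, pi_total):
        raise ValueError("need data or all of (n, S, eta_s, pi_total)")
    if n < 4:
        raise ValueError("Fu & Li tests need n >= 4")
    if S == 0:
        return float("nan"), float("nan")
    k = _fu_li_constants(n)
    Dstar = ((n / (n - 1)) * S - k["a"] * eta_s) / np.sqrt(
        k["uD"] * S + k["vD"] * S**2
    )
    Fstar = (pi_total - ((n - 1) / n) * eta_s) / np.sqrt(k["uF"] * S + k["vF"] * S**2)
    return float(Dstar), float(Fstar)


# ----------------------------------------------------------------------------
# haplotypes and recombination

def haplotype_stats(data, pop: str | None = None) -> tuple[int, float]:
    """(number of distinct haplotypes, haplotype diversity).

    Hdiv = (n/(n-1)) (1 - sum p_i^2), Nei's unbiased gene diversity over
    whole-row haplotype classes.
    """
    G = _as_matrix(data, pop)
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    classes: dict[bytes, int] = {}
    Gc = np.ascontiguousarray(G)
    for i in range(n):
        key = Gc[i].tobytes()
        classes[key] = classes.get(key, 0) + 1
    p = np.fromiter(classes.values(), dtype=float, count=len(classes)) / n
    hdiv = (1.0 - (p**2).sum()) * n / (n - 1)
    return len(classes), float(hdiv)


def _incompatible_intervals(G: np.ndarray, positions: np.ndarray | None) -> list:
    """Four-gamete-violating biallelic site pairs as (left, right) intervals."""
    counts, _ = _column_counts(G)
    biallelic = np.flatnonzero((counts > 0).sum(axis=0) == 2)
    if positions is None:
        positions = np.arange(G.shape[1])
    # recode each biallelic column to 0/1
    B = np.empty((G.shape[0], biallelic.size), dtype=np.int8)
    for j, col in enumerate(biallelic):
        B[:, j] = G[:, col] != G[0, col]
    intervals = []
    for i, j in itertools.combinations(range(biallelic.size), 2):
        pair = B[:, i] * 2 + B[:, j]
        if np.unique(pair).size == 4:
            lo, hi = sorted((positions[biallelic[i]], positions[biallelic[j]]))
            intervals.append((lo, hi))
    return intervals


def min_recombination_Rm(data, pop: str | None = None,
                         positions: np.ndarray | None = None) -> int:
    """Hudson-Kaplan four-gamete lower bound on recombination events.

    Collects all biallelic pairs showing all four gametes and returns the
    maximum number of pairwise-disjoint open intervals among them (greedy
    right-endpoint scan after discarding intervals that contain another).
    """
    G = _as_matrix(data, pop)
    intervals = _incompatible_intervals(G, positions)
    if not intervals:
        return 0
    # cull intervals that strictly contain another incompatible interval
    minimal = [
        iv for iv in intervals
        if not any(o != iv and o[0] >= iv[0] and o[1] <= iv[1] for o in intervals)
    ]
    minimal.sort(key=lambda iv: iv[1])
    rm, bound = 0, -np.inf
    for lo, hi in minimal:
        if lo >= bound:
            rm += 1
            bound = hi
    return rm


# ----------------------------------------------------------------------------
# two-population statistics

def _two_pop_matrices(data, popmap=None, pops=("wild", "cultivated")):
    if isinstance(data, FilteredAlignment):
        return _as_matrix(data, pops[0]), _as_matrix(data, pops[1])
    G = _as_matrix(data)
    labels = np.asarray(popmap)
    return G[labels == pops[0]], G[labels == pops[1]]


def fst(data, popmap=None, pops=("wild", "cultivated")) -> float:
    """Hudson-style Fst = 1 - Hw/Hb averaged over segregating sites.

    Hw is the mean of the two within-population (unbiased) heterozygosities,
    Hb the probability of mismatch between one sequence from each
    population; both are averaged over the union of segregating sites
    before the ratio is taken.  Returns 0.0 when no site segregates.
    """
    G1, G2 = _two_pop_matrices(data, popmap, pops)
    if G1.shape[0] < 2 or G2.shape[0] < 2:
        raise ValueError("need at least 2 sequences per population")
    n1, n2 = G1.shape[0], G2.shape[0]
    both = np.vstack([G1, G2])
    states = np.unique(both)
    c1 = np.stack([(G1 == s).sum(axis=0) for s in states])
    c2 = np.stack([(G2 == s).sum(axis=0) for s in states])
    seg = ((c1 + c2) > 0).sum(axis=0) > 1
    if not seg.any():
        return 0.0
    p1, p2 = c1[:, seg] / n1, c2[:, seg] / n2
    hw1 = (1 - (p1**2).sum(axis=0)) * n1 / (n1 - 1)
    hw2 = (1 - (p2**2).sum(axis=0)) * n2 / (n2 - 1)
    hw = (hw1 + hw2) / 2
    hb = 1 - (p1 * p2).sum(axis=0)
    return float(1.0 - hw.mean() / hb.mean())


def polymorphism_partition(data, popmap=None, pops=("wild", "cultivated")
                           ) -> tuple[int, int, int, int]:
    """(shared, fixed, first-pop-specific, second-pop-specific) site counts.

    Per segregating column: shared = polymorphic in both populations;
    fixed = each population monomorphic for different states; specific =
    polymorphic in exactly one.  Categories are disjoint and exhaustive.
    """
    G1, G2 = _two_pop_matrices(data, popmap, pops)
    v1 = (G1 != G1[0]).any(axis=0)
    v2 = (G2 != G2[0]).any(axis=0)
    shared = int((v1 & v2).sum())
    spec1 = int((v1 & ~v2).sum())
    spec2 = int((~v1 & v2).sum())
    fixed = int((~v1 & ~v2 & (G1[0] != G2[0])).sum())
    return shared, fixed, spec1, spec2


def ks_divergence(data, popmap=None, *, L: float | None = None,
                  pops=("wild", "cultivated"), sites: str = "silent") -> float:
    """Mean per-site difference between one sequence from each population."""
    if L is None:
        if not isinstance(data, FilteredAlignment):
            raise ValueError("L is required for bare matrices")
        L = data.L_silent if sites == "silent" else data.L_total
        if L == 0:
            raise ValueError(f"{data.locus_id}: zero {sites} length")
    G1, G2 = _two_pop_matrices(data, popmap, pops)
    states = np.unique(np.vstack([G1, G2]))
    p1 = np.stack([(G1 == s).mean(axis=0) for s in states])
    p2 = np.stack([(G2 == s).mean(axis=0) for s in states])
    mismatch = 1.0 - (p1 * p2).sum(axis=0)
    return float(mismatch.sum() / L)


def theta_ks_correlation(theta_sil, ks, exclude: set | None = None,
                         loci: list | None = None) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of silent theta vs divergence
    across loci, optionally excluding named loci."""
    theta_sil = np.asarray(theta_sil, dtype=float)
    ks = np.asarray(ks, dtype=float)
    if exclude:
        if loci is None:
            raise ValueError("loci names are required to exclude loci")
        keep = np.array([l not in exclude for l in loci])
        theta_sil, ks = theta_sil[keep], ks[keep]
    if theta_sil.size < 3:
        raise ValueError("need at least 3 loci")
    if np.allclose(theta_sil.var(), 0) or np.allclose(ks.var(), 0):
        raise ValueError("zero variance in one of the vectors")
    r, p = sps.pearsonr(theta_sil, ks)
    return float(r), float(p)


def sfs(data, pop: str | None = None, outgroup: np.ndarray | None = None,
        population: str = "") -> SFS:
    """Site-frequency spectrum over biallelic segregating sites.

    With an outgroup sequence, the non-outgroup allele at each site is
    called derived; sites where the outgroup carries a third state are
    skipped.  Without an outgroup the spectrum is folded (minor-allele
    classes 1..n//2).
    """
    G = _as_matrix(data, pop)
    n = G.shape[0]
    counts, states = _column_counts(G)
    biallelic = np.flatnonzero((counts > 0).sum(axis=0) == 2)
    polarized = outgroup is not None
    if polarized:
        out = np.asarray(outgroup)
        out = out.view(np.uint8) if out.dtype.kind == "S" else out
        spec = np.zeros(n - 1, dtype=int)
        for col in biallelic:
            present = states[counts[:, col] > 0]
            if out[col] not in present:
                continue
            derived = present[present != out[col]][0]
            k = int((G[:, col] == derived).sum())
            spec[k - 1] += 1
    else:
        spec = np.zeros(n // 2, dtype=int)
        for col in biallelic:
            k = int(counts[counts[:, col] > 0, col].min())
            spec[min(k, n - k) - 1] += 1
    return SFS(counts=spec, n=n, polarized=polarized, population=population)


# ----------------------------------------------------------------------------
# multilocus HKA

def hka_multilocus(S_a, S_b, D, n_a, n_b) -> HKAResult:
    """Multilocus HKA goodness-of-fit with polymorphism in two species.

    Inputs are per-locus counts: segregating sites in species A and B,
    between-species divergence D (mean pairwise differences between the
    species, same mutational scale), and sample sizes.  Locus-total
    mutation parameters theta_i, the scaled divergence time T and the
    population-size ratio f = N_B/N_A are fitted by solving the moment
    equations; the statistic is the summed standardized deviation over all
    3L cells, with the chi-square reference distribution on 2L-2 df as a
    rough approximation.
    """
    S_a = np.asarray(S_a, dtype=float)
    S_b = np.asarray(S_b, dtype=float)
    D = np.asarray(D, dtype=float)
    L = S_a.size
    if L < 2:
        raise ValueError("need at least 2 loci")
    if S_a.sum() == 0 and S_b.sum() == 0:
        raise ValueError("degenerate system: no polymorphism at any locus")
    a_A = np.array([harmonic(n) for n in np.broadcast_to(n_a, (L,))])
    a_B = np.array([harmonic(n) for n in np.broadcast_to(n_b, (L,))])
    b_A = np.array([harmonic2(n) for n in np.broadcast_to(n_a, (L,))])
    b_B = np.array([harmonic2(n) for n in np.broadcast_to(n_b, (L,))])

    def unpack(x):
        return np.exp(x[:L]), np.exp(x[L]), np.exp(x[L + 1])

    def residuals(x):
        theta, T, f = unpack(x)
        div_scale = T + (1 + f) / 2
        r_tot_a = S_a.sum() - (theta * a_A).sum()
        r_tot_b = S_b.sum() - f * (theta * a_B).sum()
        r_tot_d = D.sum() - (theta * div_scale).sum()
        r_loc = (S_a + S_b + D) - theta * (a_A + f * a_B + div_scale)
        return np.concatenate([[r_tot_a, r_tot_b, r_tot_d], r_loc[1:]])

    theta0 = np.maximum(S_a / a_A, 0.5)
    f0 = max((S_b.sum() / a_B.mean()) / max(S_a.sum() / a_A.mean(), 1e-9), 1e-3)
    T0 = max(D.sum() / theta0.sum() - (1 + f0) / 2, 0.05)
    from scipy.optimize import least_squares

    x0 = np.log(np.concatenate([theta0, [T0, f0]]))
    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    theta, T, f = unpack(sol.x)
    div_scale = T + (1 + f) / 2
    E_a, E_b, E_d = theta * a_A, f * theta * a_B, theta * div_scale
    V_a = E_a + (theta**2) * b_A
    V_b = E_b + (f * theta) ** 2 * b_B
    V_d = E_d + (theta * (1 + f) / 2) ** 2
    comp = np.stack(
        [(S_a - E_a) ** 2 / V_a, (S_b - E_b) ** 2 / V_b, (D - E_d) ** 2 / V_d],
        axis=1,
    )
    chi2 = float(comp.sum())
    df = 3 * L - (L + 2)
    return HKAResult(
        chi2=chi2, n_loci=L, components=comp, theta=theta, T=float(T), f=float(f),
        df=df, p_value=float(sps.chi2.sf(chi2, df)),
    )


# ----------------------------------------------------------------------------
# one-call locus summary

def summarize_locus(aln: FilteredAlignment, pop: str, rho_hat: float = np.nan
                    ) -> LocusSummary:
    """All summary-table-style statistics for one locus and one population."""
    G = _as_matrix(aln, pop)
    n = G.shape[0]
    S = segregating_sites(G)
    pi_tot = mean_pairwise_differences(G)
    hap, hdiv = haplotype_stats(G)
    Dstar, Fstar = fu_li_tests(G) if S else (np.nan, np.nan)
    return LocusSummary(
        locus_id=aln.locus_id,
        n=n,
        L_total=aln.L_total,
        L_silent=aln.L_silent,
        S=S,
        pi=pi_tot / aln.L_total,
        pi_silent=pi_tot / aln.L_silent if aln.L_silent else np.nan,
        theta_w=watterson_theta(S, n, aln.L_total),
        theta_w_silent=(
            watterson_theta(S, n, aln.L_silent) if aln.L_silent else np.nan
        ),
        tajima_D=tajimas_D(n=n, S=S, pi_total=pi_tot) if S else np.nan,
        fuli_Dstar=Dstar,
        fuli_Fstar=Fstar,
        rho_hat=rho_hat,
        Rm=min_recombination_Rm(G, positions=aln.kept_columns),
        Hap=hap,
        Hdiv=hdiv,
    )
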
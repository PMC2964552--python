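"""Neutral coalescent simulation for the domestication-bottleneck model.

The demographic model is the split-with-bottleneck-and-migration history
used in multilocus domestication studies: an ancestral population of
effective size N_a; at t2 generations ago a founder population of size N_b
splits off, expands to N_p at t1 = t2 - d, and both populations evolve at
constant size to the present with migration (4Nm-scaled rates m12, m21)
active between the split and the present.  The bottleneck severity is
k = N_b / d: small k means few founders for a long time, i.e. a severe
bottleneck.

Simulation is delegated to msprime.  The hot path uses the ms-compatible
``msprime.simulate`` API so that the mutation process runs in C and the
nine loci of one parameter draw are generated as replicates of a single
maximal configuration (largest sample sizes and locus length), from which
each locus takes a prefix of rows per population and the sites below its
own length — exact under the sampling consistency of the coalescent and
the restriction property of the recombinant genealogy.

Samples are haploid sequences; with ``Ne`` the (diploid) effective size the
expected per-site diversity is 4*Ne*mu, matching the ms convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import msprime
import numpy as np

__all__ = [
    "DemographicModel",
    "LocusSpec",
    "HaplotypeMatrix",
    "simulate_standard",
    "simulate_standard_fast",
    "simulate_bottleneck",
    "simulate_bottleneck_panel",
    "simulate_bottleneck_panel_fast",
    "summarize",
    "generations_to_coalescent",
    "coalescent_to_generations",
]

WILD, CULT = 0, 1


@dataclass(frozen=True)
class DemographicModel:
    """Split-with-bottleneck-and-migration demography.

    Parameters are in natural units: effective sizes in (diploid-equivalent)
    individuals, times in generations before present, mu in per-site
    per-generation mutations.  m12 is the wild-to-cultivar migration rate and
    m21 the reverse, both 4*N_a*m scaled (ms convention).  rho_over_theta
    sets the per-site recombination rate as a multiple of mu.
    """

    N_a: float
    mu: float = 7e-9
    rho_over_theta: float = 1.0
    t2: float = 8000.0
    d: float = 1000.0
    k: float = 0.6
    N_p: float | None = None
    m12: float = 0.0
    m21: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0 or self.t2 <= self.d:
            raise ValueError("need t2 > d > 0 (so that t1 = t2 - d >= 0)")
        if min(self.N_a, self.k, self.mu) <= 0:
            raise ValueError("N_a, k and mu must be positive")

    @property
    def t1(self) -> float:
        return self.t2 - self.d

    @property
    def N_b(self) -> float:
        return self.k * self.d

    @property
    def N_p_effective(self) -> float:
        return self.N_a if self.N_p is None else self.N_p

    @property
    def theta_site(self) -> float:
        return 4 * self.N_a * self.mu

    @classmethod
    def from_theta(cls, theta_site: float, mu: float = 7e-9, **kw) -> "DemographicModel":
        """Anchor N_a to an observed per-site theta via theta = 4*N_a*mu."""
        return cls(N_a=theta_site / (4 * mu), mu=mu, **kw)

    def with_(self, **kw) -> "DemographicModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class LocusSpec:
    """Per-locus simulation geometry: lengths in bp, sample sizes in
    haplotypes.  L_wild / L_cult are the species-specific analyzable spans
    (they may differ because alignment trimming differs); L_total is the
    simulated span, max of the two."""

    locus_id: str
    L_wild: float
    L_cult: float
    n_wild: int
    n_cult: int
    L_silent: float | None = None
    theta_site: float | None = None  # per-locus per-site theta for simulation

    @property
    def L_total(self) -> float:
        return max(self.L_wild, self.L_cult)


@dataclass
class HaplotypeMatrix:
    """Binary infinite-sites haplotypes: rows = samples, columns = sites."""

    genotypes: np.ndarray  # (n, S) int8, 0 ancestral / 1 derived
    positions: np.ndarray  # bp coordinates, strictly increasing
    pops: np.ndarray  # per-row population code (WILD/CULT)
    L: float

    def rows(self, pop: int | None = None) -> np.ndarray:
        if pop is None:
            return self.genotypes
        return self.genotypes[self.pops == pop]

    def restrict(self, n_wild: int, n_cult: int, L: float) -> "HaplotypeMatrix":
        """Take the first n rows of each population and sites below L,
        dropping columns monomorphic in the retained rows."""
        keep_rows = np.concatenate(
            [np.flatnonzero(self.pops == WILD)[:n_wild],
             np.flatnonzero(self.pops == CULT)[:n_cult]]
        )
        G = self.genotypes[keep_rows]
        site_mask = self.positions < L
        G = G[:, site_mask]
        poly = (G != G[0]).any(axis=0)
        return HaplotypeMatrix(
            genotypes=np.ascontiguousarray(G[:, poly]),
            positions=self.positions[site_mask][poly],
            pops=self.pops[keep_rows],
            L=L,
        )


def generations_to_coalescent(t: float, N_a: float) -> float:
    """Generations before present -> time in units of 4*N_a generations."""
    return t / (4.0 * N_a)


def coalescent_to_generations(tau: float, N_a: float) -> float:
    return tau * 4.0 * N_a


def _from_ts(ts, pops: np.ndarray, L: float) -> HaplotypeMatrix:
    G = ts.genotype_matrix().T.astype(np.int8)
    return HaplotypeMatrix(
        genotypes=np.ascontiguousarray(G),
        positions=ts.tables.sites.position.copy(),
        pops=pops,
        L=L,
    )


def _legacy(**kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return msprime.simulate(**kw)


def simulate_standard(n: int, theta_locus: float, rho_locus: float, L: float,
                      seed: int, num_replicates: int | None = None):
    """Constant-size neutral coalescent sample, infinite-sites mutations.

    theta_locus and rho_locus are ms-scaled locus totals (4*N*u_locus,
    4*N*c_locus).  Returns one HaplotypeMatrix, or an iterator of them when
    num_replicates is given.  Reproducible and bit-identical under a fixed
    seed.
    """
    if n < 2 or theta_locus < 0 or rho_locus < 0:
        raise ValueError("need n >= 2 and nonnegative theta, rho")
    N0 = 1e4  # arbitrary; cancels in the scaled rates
    reps = _legacy(
        sample_size=n,
        Ne=N0,
        length=L,
        mutation_rate=theta_locus / (4 * N0 * L),
        recombination_rate=rho_locus / (4 * N0 * L),
        num_replicates=num_replicates or 1,
        random_seed=int(seed),
    )
    pops = np.zeros(n, dtype=np.int8)
    gen = (_from_ts(ts, pops, L) for ts in reps)
    return gen if num_replicates else next(gen)


def _bottleneck_config(model: DemographicModel, n_wild: int, n_cult: int):
    """Legacy-API configuration for the two-population bottleneck model."""
    pc = [
        msprime.PopulationConfiguration(sample_size=n_wild,
                                        initial_size=model.N_a),
        msprime.PopulationConfiguration(sample_size=n_cult,
                                        initial_size=model.N_p_effective),
    ]
    # migration_matrix[j][k]: backwards rate of lineages in j moving to k.
    # Forward wild->cultivar migration (m12) places cultivar lineages'
    # parents in the wild population.
    m = 1.0 / (4 * model.N_a)
    mig = [[0.0, model.m21 * m], [model.m12 * m, 0.0]]
    events = [
        msprime.PopulationParametersChange(
            time=model.t1, initial_size=model.N_b, population_id=CULT),
        msprime.MassMigration(
            time=model.t2, source=CULT, destination=WILD, proportion=1.0),
        msprime.MigrationRateChange(time=model.t2, rate=0.0),
    ]
    return pc, mig, events


def simulate_bottleneck_panel(model: DemographicModel, specs, seed: int,
                              num_replicates: int | None = None):
    """Simulate one replicate of every locus in ``specs`` under ``model``.

    All loci are drawn as independent replicates of the maximal
    configuration (largest n_wild, n_cult, L in the panel) and restricted
    to each locus's own geometry.  Returns a list of HaplotypeMatrix, or an
    iterator of such lists when num_replicates is given.
    """
    specs = list(specs)
    n_w = max(s.n_wild for s in specs)
    n_c = max(s.n_cult for s in specs)
    L = max(s.L_total for s in specs)
    pc, mig, events = _bottleneck_config(model, n_w, n_c)
    k = len(specs)
    total = k * (num_replicates or 1)
    reps = _legacy(
        population_configurations=pc,
        migration_matrix=mig,
        demographic_events=events,
        Ne=model.N_a,
        length=L,
        mutation_rate=model.mu,
        recombination_rate=model.rho_over_theta * model.mu,
        num_replicates=total,
        random_seed=int(seed),
    )
    pops = np.concatenate([np.full(n_w, WILD, np.int8), np.full(n_c, CULT, np.int8)])

    def batches():
        it = iter(reps)
        while True:
            panel = []
            for s in specs:
                try:
                    ts = next(it)
                except StopIteration:
                    return
                panel.append(_from_ts(ts, pops, L).restrict(
                    s.n_wild, s.n_cult, s.L_total))
            yield panel

    gen = batches()
    return gen if num_replicates else next(gen)


def simulate_bottleneck(model: DemographicModel, spec: LocusSpec, seed: int,
                        num_replicates: int | None = None):
    """Joint wild + cultivated sample for a single locus under ``model``."""
    out = simulate_bottleneck_panel(model, [spec], seed,
                                    num_replicates=num_replicates)
    if num_replicates:
        return (panel[0] for panel in out)
    return out[0]


def simulate_standard_fast(n: int, theta_locus: float, rho_locus: float,
                           L: float, seed: int) -> HaplotypeMatrix:
    """As :func:`simulate_standard` but on the numba Hudson engine
    (:mod:`milletpop.fastcoal`); used by the rejection-ABC hot loops."""
    from .fastcoal import sim_locus_matrix

    G, pos = sim_locus_matrix(n, 0, theta_locus, rho_locus, seed, L=L)
    return HaplotypeMatrix(genotypes=G, positions=pos,
                           pops=np.zeros(n, dtype=np.int8), L=L)


def simulate_bottleneck_panel_fast(model: DemographicModel, specs,
                                   seed: int) -> list[HaplotypeMatrix]:
    """One replicate of every locus under ``model`` on the fast engine.

    Each locus uses its own per-site theta (``spec.theta_site``, falling
    back to the model's) with rho = rho_over_theta * theta, i.e. mutation
    rate heterogeneity among loci is part of the model.
    """
    from .fastcoal import sim_locus_matrix

    Na = model.N_a
    tau1 = generations_to_coalescent(model.t1, Na)
    tau2 = generations_to_coalescent(model.t2, Na)
    x2p = model.N_p_effective / Na
    x2b = model.N_b / Na
    out = []
    for i, spec in enumerate(specs):
        theta_site = spec.theta_site or model.theta_site
        L = spec.L_total
        G, pos = sim_locus_matrix(
            spec.n_wild, spec.n_cult,
            theta_site * L, model.rho_over_theta * theta_site * L,
            (seed + 1000003 * i) & 0x7FFFFFFF, L=L,
            x2_present=x2p, x2_bottleneck=x2b, tau1=tau1, tau2=tau2,
            m12=model.m12, m21=model.m21)
        pops = np.concatenate([np.full(spec.n_wild, WILD, np.int8),
                               np.full(spec.n_cult, CULT, np.int8)])
        out.append(HaplotypeMatrix(genotypes=G, positions=pos, pops=pops, L=L))
    return out


def summarize(hm: HaplotypeMatrix, pop: int | None = None,
              L: float | None = None, with_rho: bool = False) -> dict:
    """Summary-statistic vector element (S, pi, Hap, Hdiv[, rho_hat]) of one
    simulated locus, computed with the same statistic kernels used for
    observed alignments.  pi is per site over ``L`` (default: the matrix's
    own span)."""
    from . import popstats
    from .ld import rho_hat_per_locus

    G = hm.rows(pop)
    n = G.shape[0]
    positions = hm.positions
    L = float(L if L is not None else hm.L)
    if L < hm.L:
        in_win = positions < L
        G, positions = G[:, in_win], positions[in_win]
    poly = (G != G[0]).any(axis=0)
    Gp = G[:, poly]
    S = int(poly.sum())
    if S:
        counts = Gp.sum(axis=0)
        p = counts / n
        pi = float((2 * p * (1 - p)).sum() * n / (n - 1) / L)
    else:
        pi = 0.0
    hap, hdiv = popstats.haplotype_stats(G)
    out = {"S": S, "pi": pi, "Hap": hap, "Hdiv": hdiv}
    if with_rho:
        out["rho_hat"] = rho_hat_per_locus(
            Gp, positions=positions[poly], L=L) if S else float("nan")
    return out
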
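"""Rejection approximate Bayesian computation for the domestication model.

Three analyses are provided, mirroring a two-species multilocus survey:

* ``abc_standard`` — posterior for the per-site population mutation rate
  theta and recombination rate rho (and their ratio) of one species under
  the standard neutral model, accepting a draw when at least 3 of the 4
  cross-locus mean statistics (S, pi, Hap, Hdiv) fall within a 20%
  multiplicative tolerance of the observed means.
* ``abc_bottleneck`` — two-stage inference of the bottleneck parameters
  (t2, d, k, m12, m21) on a fixed rho/theta grid value.  Stage 1 accepts a
  draw when the cross-locus mean AND variance of each of (S, pi, Hap,
  Hdiv) for the wild sample fall within 30% of the observed wild values;
  stage 2 keeps accepted draws whose cultivated means of (S, rho_hat, Hap,
  Hdiv) satisfy a 3-of-4 30% rule.  The bottleneck severity k = N_b/d is
  the identifiable quantity of interest.
* ``selection_scan`` — posterior-predictive per-locus p-value: the
  fraction of replicates, with parameters resampled from the bottleneck
  posterior, whose simulated cultivated diversity is at most the observed
  locus value.  Small p flags diversity loss beyond what the demographic
  model explains.

"Within x%" is multiplicative: |sim - obs| <= x * |obs|; when obs = 0 the
criterion falls back to |sim| <= x * (cross-locus SD of that statistic).
All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .coalescent import (CULT, WILD, DemographicModel, LocusSpec,
                         simulate_bottleneck_panel_fast,
                         simulate_standard_fast, summarize)
from .tables import Observation, load_observed_from_table, panel_locus_specs

__all__ = ["Uniform", "PriorSpec", "ABCPosterior", "abc_standard",
           "abc_bottleneck", "posterior_mode", "selection_scan",
           "load_observed_from_table"]

_STANDARD_STATS = ("S", "pi", "Hap", "Hdiv")
_STAGE2_STATS = ("S", "rho_hat", "Hap", "Hdiv")
_STAGE2_OBS_KEYS = {"rho_hat": "rho"}


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"need low < high, got ({self.low}, {self.high})")

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))

    def contains(self, x) -> bool:
        return bool(np.all((self.low <= np.asarray(x))
                           & (np.asarray(x) <= self.high)))


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior boxes.  theta/rho are per-site; t2 and d are in
    generations; k = N_b/d; migration rates are 4Nm-scaled."""

    theta: Uniform = Uniform(0.0, 0.03)
    rho: Uniform = Uniform(0.0, 0.15)
    t2: Uniform = Uniform(5000.0, 15000.0)
    d: Uniform = Uniform(100.0, 3000.0)
    k: Uniform = Uniform(0.1, 10.0)
    m12: Uniform = Uniform(0.0, 100.0)
    m21: Uniform = Uniform(0.0, 100.0)


@dataclass
class ABCPosterior:
    """Accepted parameter draws plus run metadata."""

    draws: pd.DataFrame
    parameters: list[str]
    n_accepted: int
    n_draws_total: int
    tolerance: dict
    seed: int
    priors: PriorSpec
    rho_over_theta: float | None = None
    stage1_accepted: int | None = None
    extra: dict = field(default_factory=dict)

    def support(self, param: str) -> Uniform | None:
        box = getattr(self.priors, param, None)
        if box is None and param == "rho_over_theta":
            return None
        return box

    def mode(self, param: str) -> float:
        box = self.support(param)
        return posterior_mode(self.draws[param].to_numpy(),
                              support=(box.low, box.high) if box else None)

    def median(self, param: str) -> float:
        return float(self.draws[param].median())

    def interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        q = (1 - level) / 2
        x = self.draws[param]
        return float(x.quantile(q)), float(x.quantile(1 - q))

    def is_flat(self, param: str, ratio: float = 1.2) -> bool:
        x = self.draws[param].to_numpy()
        box = self.support(param)
        dens = _kde_grid(x, (box.low, box.high) if box else None)[1]
        return bool(dens.max() / np.median(dens) < ratio)


def _kde_grid(x: np.ndarray, support=None, n_grid: int = 512):
    kde = gaussian_kde(x, bw_method="silverman")
    lo, hi = (x.min(), x.max()) if support is None else support
    lo, hi = max(lo, x.min() - 3 * x.std()), min(hi, x.max() + 3 * x.std())
    grid = np.linspace(lo, hi, n_grid)
    return grid, kde(grid)


def posterior_mode(draws: np.ndarray, support=None) -> float:
    """Gaussian-KDE (Silverman bandwidth) density mode on a grid over the
    prior-truncated support."""
    x = np.asarray(draws, dtype=float)
    if x.size < 50:
        raise ValueError(f"too few draws for a density mode ({x.size} < 50)")
    grid, dens = _kde_grid(x, support)
    return float(grid[int(np.argmax(dens))])


def _within(sim: float, obs: float, tol: float, sd: float) -> bool:
    if np.isnan(sim):
        return False
    if obs == 0:
        return abs(sim) <= tol * sd
    return abs(sim - obs) <= tol * abs(obs)


def _check_rate(n_accepted: int, n_total: int, context: str,
                floor: float = 1e-5, min_total: int = 200_000) -> None:
    if n_total >= min_total and n_accepted / n_total < floor:
        raise RuntimeError(
            f"{context}: acceptance rate {n_accepted}/{n_total} "
            f"< {floor}; observed statistics are unreachable under the prior "
            "— check the observation scale and tolerances")


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


# ---------------------------------------------------------------------------
# standard-model ABC

def abc_standard(observed: Observation, priors: PriorSpec | None = None,
                 *, n_accept: int = 1000, tol: float = 0.20,
                 min_within: int = 3, seed: int = 1,
                 max_draws: int = 2_000_000,
                 locus_specs: list[tuple[str, int, float]] | None = None
                 ) -> ABCPosterior:
    """Rejection ABC for (theta, rho) under the standard neutral model.

    Each draw simulates every locus of the panel at its own sample size and
    length and is accepted when at least ``min_within`` of the 4 cross-locus
    mean statistics lie within ``tol`` of the observed means.
    """
    priors = priors or PriorSpec()
    if locus_specs is None:
        from .tables import species_locus_specs
        locus_specs = species_locus_specs(observed)
    # cheapest (shortest) loci first: simulation cost grows superlinearly
    # with locus length at high recombination, and most draws are rejected
    # early on partial sums, so rejected draws then burn the cheap loci
    locus_specs = sorted(locus_specs, key=lambda x: x[2])
    obs = {s: observed.means[s] for s in _STANDARD_STATS}
    sd = {s: float(np.sqrt(observed.variances[s])) for s in _STANDARD_STATS}
    rng = np.random.default_rng(seed)
    rows, n_total = [], 0
    while len(rows) < n_accept:
        if n_total >= max_draws:
            raise RuntimeError(
                f"abc_standard: draw budget exhausted ({len(rows)}/{n_accept} "
                f"accepted in {n_total} draws)")
        n_total += 1
        theta = priors.theta.sample(rng)
        rho = priors.rho.sample(rng)
        base_seed = _spawn_seed(rng)
        stats = {s: [] for s in _STANDARD_STATS}
        n_loci = len(locus_specs)
        # every statistic is a sum of nonnegative per-locus terms, so once a
        # partial sum exceeds the upper acceptance band the statistic has
        # definitively failed; with > (4 - min_within) definitive failures
        # the draw cannot be accepted and the remaining loci are skipped
        upper = {s: (obs[s] + tol * abs(obs[s]) if obs[s] != 0
                     else tol * sd[s]) * n_loci for s in _STANDARD_STATS}
        aborted = False
        for i, (_, n_i, L_i) in enumerate(locus_specs):
            hm = simulate_standard_fast(
                n_i, theta * L_i, rho * L_i, L_i,
                (base_seed + 1000003 * i) & 0x7FFFFFFF)
            loc = summarize(hm, WILD)
            for s in _STANDARD_STATS:
                stats[s].append(loc[s])
            failed = sum(sum(stats[s]) > upper[s] for s in _STANDARD_STATS)
            if failed > 4 - min_within:
                aborted = True
                break
        if aborted:
            _check_rate(len(rows), n_total, "abc_standard")
            continue
        means = {s: float(np.mean(v)) for s, v in stats.items()}
        hits = sum(_within(means[s], obs[s], tol, sd[s])
                   for s in _STANDARD_STATS)
        if hits >= min_within:
            rows.append({"theta": theta, "rho": rho,
                         "rho_over_theta": rho / theta if theta else np.nan,
                         **{f"mean_{s}": means[s] for s in _STANDARD_STATS}})
        _check_rate(len(rows), n_total, "abc_standard")
    return ABCPosterior(
        draws=pd.DataFrame(rows),
        parameters=["theta", "rho", "rho_over_theta"],
        n_accepted=len(rows), n_draws_total=n_total,
        tolerance={"tol": tol, "min_within": min_within},
        seed=seed, priors=priors,
    )


# ---------------------------------------------------------------------------
# two-stage bottleneck ABC

def abc_bottleneck(observed_wild: Observation, observed_cult: Observation,
                   priors: PriorSpec | None = None, *,
                   rho_over_theta: float = 1.0,
                   n_stage1: int = 2000, tol_stage1: float | None = None,
                   tol_stage2: float = 0.30, min_within_stage2: int = 3,
                   seed: int = 1, mu: float = 7e-9,
                   theta_site: float | None = None,
                   N_p: float | None = None,
                   specs: list[LocusSpec] | None = None,
                   min_survivors: int = 0,
                   max_draws: int = 4_000_000) -> ABCPosterior:
    """Two-stage rejection ABC for the bottleneck parameters.

    Stage 1 draws (t2, d, k, m12, m21) from the priors, simulates the
    two-population model for every locus, and accepts when both the mean
    and the variance (across loci) of each of (S, pi, Hap, Hdiv) for the
    WILD sample fall within ``tol_stage1`` of the observed wild values
    (default 0.30, widened to 0.60 for rho/theta >= 2 where acceptance
    becomes rare).  Stage 2 keeps the accepted draws whose CULTIVATED
    cross-locus means of (S, rho_hat, Hap, Hdiv) satisfy a
    ``min_within_stage2``-of-4 ``tol_stage2`` rule.

    The ancestral size is anchored to the wild observation,
    N_a = theta_site / (4 mu), with theta_site defaulting to the observed
    wild cross-locus mean Watterson theta.

    ``min_survivors`` optionally extends stage 1 past ``n_stage1`` (at
    most 2x) until that many stage-2 survivors exist, so that the
    posterior density mode (which needs >= 50 draws) rests on a stable
    sample.
    """
    priors = priors or PriorSpec()
    if tol_stage1 is None:
        tol_stage1 = 0.60 if rho_over_theta >= 2 else 0.30
    specs = specs or panel_locus_specs(
        {"wild": observed_wild, "cultivated": observed_cult})
    theta_site = theta_site if theta_site is not None \
        else observed_wild.mean_theta
    base = DemographicModel.from_theta(
        theta_site, mu=mu, rho_over_theta=rho_over_theta, N_p=N_p)
    obs_w = {s: observed_wild.means[s] for s in _STANDARD_STATS}
    var_w = {s: observed_wild.variances[s] for s in _STANDARD_STATS}
    sd_w = {s: float(np.sqrt(v)) for s, v in var_w.items()}
    obs_c, sd_c = {}, {}
    for s in _STAGE2_STATS:
        key = _STAGE2_OBS_KEYS.get(s, s)
        obs_c[s] = observed_cult.means[key]
        sd_c[s] = float(np.sqrt(observed_cult.variances[key]))

    rng = np.random.default_rng(seed)
    rows, n_total, n_surv = [], 0, 0
    # optional guard: keep drawing past n_stage1 (up to 2x) until enough
    # stage-2 survivors exist for a stable density mode
    while len(rows) < n_stage1 or (n_surv < min_survivors
                                   and len(rows) < 2 * n_stage1):
        if n_total >= max_draws:
            raise RuntimeError(
                f"abc_bottleneck: draw budget exhausted ({len(rows)}/"
                f"{n_stage1} stage-1 acceptances in {n_total} draws)")
        n_total += 1
        params = {p: getattr(priors, p).sample(rng)
                  for p in ("t2", "d", "k", "m12", "m21")}
        model = base.with_(**params)
        panel = simulate_bottleneck_panel_fast(model, specs, _spawn_seed(rng))
        wild = {s: [] for s in _STANDARD_STATS}
        for spec, hm in zip(specs, panel):
            loc = summarize(hm, WILD, L=spec.L_wild)
            for s in _STANDARD_STATS:
                wild[s].append(loc[s])
        ok = True
        for s in _STANDARD_STATS:
            v = np.asarray(wild[s], dtype=float)
            if not (_within(float(v.mean()), obs_w[s], tol_stage1, sd_w[s])
                    and _within(float(v.var(ddof=1)), var_w[s], tol_stage1,
                                var_w[s] or 1.0)):
                ok = False
                break
        if not ok:
            _check_rate(len(rows), n_total, "abc_bottleneck stage 1")
            continue
        cult = {s: [] for s in _STAGE2_STATS}
        for spec, hm in zip(specs, panel):
            loc = summarize(hm, CULT, L=spec.L_cult, with_rho=True)
            for s in _STAGE2_STATS:
                cult[s].append(loc[s])
        cmeans = {s: float(np.nanmean(np.asarray(v, dtype=float)))
                  if np.isfinite(np.asarray(v, dtype=float)).any() else np.nan
                  for s, v in cult.items()}
        hits = sum(_within(cmeans[s], obs_c[s], tol_stage2, sd_c[s])
                   for s in _STAGE2_STATS)
        if hits >= min_within_stage2:
            n_surv += 1
        rows.append({**params, "stage2_hits": hits,
                     **{f"cult_mean_{s}": cmeans[s] for s in _STAGE2_STATS}})
    draws = pd.DataFrame(rows)
    survivors = draws[draws["stage2_hits"] >= min_within_stage2].reset_index(
        drop=True)
    return ABCPosterior(
        draws=survivors,
        parameters=["t2", "d", "k", "m12", "m21"],
        n_accepted=len(survivors), n_draws_total=n_total,
        tolerance={"tol_stage1": tol_stage1, "tol_stage2": tol_stage2,
                   "min_within_stage2": min_within_stage2},
        seed=seed, priors=priors, rho_over_theta=rho_over_theta,
        stage1_accepted=len(draws),
        extra={"theta_site": theta_site, "mu": mu, "N_a": base.N_a,
               "stage1_draws": draws},
    )


# ---------------------------------------------------------------------------
# posterior-predictive selection scan

def selection_scan(observed_value: float, posterior: ABCPosterior,
                   spec: LocusSpec, *, n_pp: int = 1000, seed: int = 1,
                   stat: str = "pi") -> float:
    """Posterior-predictive p-value for diversity loss at one locus.

    Parameters are resampled (with replacement) from the bottleneck
    posterior; for each replicate one locus is simulated and the cultivated
    per-site pi (or S, with ``stat='S'``) is compared with the observed
    value.  p = fraction of replicates with simulated value <= observed.
    """
    if stat not in ("pi", "S"):
        raise ValueError("stat must be 'pi' or 'S'")
    if len(posterior.draws) == 0:
        raise ValueError("empty posterior")
    rng = np.random.default_rng(seed)
    theta_site = posterior.extra["theta_site"]
    mu = posterior.extra["mu"]
    base = DemographicModel.from_theta(
        theta_site, mu=mu, rho_over_theta=posterior.rho_over_theta or 1.0)
    idx = rng.integers(0, len(posterior.draws), size=n_pp)
    hits = 0
    for i in idx:
        row = posterior.draws.iloc[int(i)]
        model = base.with_(**{p: float(row[p]) for p in
                              ("t2", "d", "k", "m12", "m21")})
        panel = simulate_bottleneck_panel_fast(model, [spec], _spawn_seed(rng))
        val = summarize(panel[0], CULT, L=spec.L_cult)[stat]
        if val <= observed_value:
            hits += 1
    return hits / n_pp
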
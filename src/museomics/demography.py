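"""Drift-only temporal Ne estimation and an analytic expected-pi diagnostic.

The estimator compares the observed mean absolute allele-frequency change
between two temporal samples against Fisher-Wright forward simulations:

1. each site's initial population frequency is drawn from a Bayesian
   posterior combining the observed sample counts with a mutation-drift
   equilibrium (or uniform) prior on a discrete frequency grid;
2. frequencies are resampled binomially for G generations at candidate
   haploid size N* (G = years x 15 generations per year);
3. terminal sampling mirrors the data: an individual-sequencing cohort
   draws n alleles; a pool-seq cohort draws 240 pool alleles and then
   n_eff reads from that pool (two-stage sampling adds variance);
4. N* is chosen on a coarse grid (1,000..20,000 step 1,000; 1,000
   replicates each) to minimize |simulated - observed mean |dp||, then
   refined +/-500 in steps of 100.

The drift-only model's adequacy is checked by comparing observed pi with
the expectation under the fitted piecewise-constant history, computed from
epoch-wise integration of the pairwise coalescence time.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

MU_DEFAULT = 5.21e-10  # per site per generation
GENERATIONS_PER_YEAR = 15
FREQ_GRID_SIZE = 512


@dataclass
class TemporalFreqData:
    """Per-site allele counts at two time points plus the interval length."""

    count_t0: np.ndarray
    n_t0: np.ndarray
    count_t1: np.ndarray
    n_t1: np.ndarray
    generations: int

    def __post_init__(self) -> None:
        for c, n in ((self.count_t0, self.n_t0), (self.count_t1, self.n_t1)):
            if np.any(c > n):
                raise ValueError("allele count exceeds sample size")
        if self.generations <= 0:
            raise ValueError("generations must be positive")

    def segregating_at_t0(self) -> np.ndarray:
        return (self.count_t0 > 0) & (self.count_t0 < self.n_t0)


@dataclass
class TerminalDesign:
    """How the final generation is sampled: individuals or a read pool."""

    kind: str  # "individual" | "pool"
    n: int  # alleles drawn (individual) or effective alleles (pool)
    pool_alleles: int = 240

    def __post_init__(self) -> None:
        if self.kind not in ("individual", "pool"):
            raise ValueError("terminal design must be 'individual' or 'pool'")


@dataclass
class NeFitResult:
    grid: np.ndarray
    sim_delta: np.ndarray
    observed_delta: float
    refined_grid: np.ndarray
    refined_delta: np.ndarray
    n_star: int  # haploid effective size
    replicates: int
    at_boundary: bool = False

    @property
    def diploid_ne(self) -> float:
        return self.n_star / 2.0


def generations_between(year0: int, year1: int, per_year: int = GENERATIONS_PER_YEAR) -> int:
    """Fly generations in a calendar interval (15 per year by default)."""
    if year1 <= year0:
        raise ValueError("year1 must be after year0")
    return (year1 - year0) * per_year


def frequency_grid(size: int = FREQ_GRID_SIZE) -> np.ndarray:
    """Equally spaced interior frequencies on (0, 1)."""
    return np.arange(1, size + 1) / (size + 1)


def equilibrium_prior(grid: np.ndarray) -> np.ndarray:
    """Mutation-drift equilibrium prior density on the grid, normalized.

    The neutral frequency spectrum for a site under recurrent mutation is
    proportional to 1/f + 1/(1-f) (both allele labelings folded together);
    the mutation-rate constant cancels in the normalization.
    """
    dens = 1.0 / grid + 1.0 / (1.0 - grid)
    return dens / dens.sum()


def posterior_initial_freq(
    count: int,
    n: int,
    prior_kind: str = "equilibrium",
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Discrete posterior of the initial population frequency.

    posterior(f) proportional to prior(f) * Binomial(count | n, f) on the
    frequency grid.
    """
    if n <= 0:
        raise ValueError("sample size n must be positive")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    grid = frequency_grid() if grid is None else grid
    if prior_kind == "equilibrium":
        prior = equilibrium_prior(grid)
    elif prior_kind == "uniform":
        prior = np.full(grid.size, 1.0 / grid.size)
    else:
        raise ValueError(f"unknown prior {prior_kind!r}")
    loglik = count * np.log(grid) + (n - count) * np.log1p(-grid)
    logpost = np.log(prior) + loglik
    post = np.exp(logpost - logpost.max())
    return post / post.sum()


def _sample_initial(
    counts: np.ndarray,
    ns: np.ndarray,
    replicates: int,
    prior_kind: str,
    rng: np.random.Generator,
    grid: np.ndarray,
) -> np.ndarray:
    """(replicates, n_sites) initial frequencies drawn from site posteriors."""
    n_sites = counts.size
    out = np.empty((replicates, n_sites))
    cache: dict[tuple[int, int], np.ndarray] = {}
    for s in range(n_sites):
        key = (int(counts[s]), int(ns[s]))
        post = cache.get(key)
        if post is None:
            post = posterior_initial_freq(*key, prior_kind=prior_kind, grid=grid)
            cache[key] = post
        out[:, s] = rng.choice(grid, size=replicates, p=post)
    return out


def simulate_fw_delta(
    counts_t0: np.ndarray,
    n_t0: np.ndarray,
    n_star: int,
    generations: int,
    terminal: TerminalDesign,
    replicates: int = 1000,
    seed: int | np.random.Generator = 0,
    prior_kind: str = "equilibrium",
    grid: np.ndarray | None = None,
) -> float:
    """Simulated mean |dp| under drift at haploid size N*.

    Sites are treated as independent (linkage equilibrium). Frequencies
    absorbed at 0 or 1 stop changing; the generation loop short-circuits
    once every trajectory is absorbed.
    """
    if n_star < 1:
        raise ValueError("N* must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    grid = frequency_grid() if grid is None else grid
    counts_t0 = np.asarray(counts_t0, dtype=np.int64)
    n_t0 = np.broadcast_to(np.asarray(n_t0, dtype=np.int64), counts_t0.shape)
    p0_obs = counts_t0 / n_t0
    f = _sample_initial(counts_t0, n_t0, replicates, prior_kind, rng, grid)
    # absorbed trajectories (f in {0,1}) never move again: iterate only the
    # still-segregating entries of the flattened (replicate, site) array
    shape = f.shape
    flat = f.reshape(-1)
    active = np.flatnonzero((flat > 0.0) & (flat < 1.0))
    for _ in range(generations):
        if active.size == 0:
            break
        fa = rng.binomial(n_star, flat[active]) / n_star
        flat[active] = fa
        seg = (fa > 0.0) & (fa < 1.0)
        if not seg.all():
            active = active[seg]
    f = flat.reshape(shape)
    if terminal.kind == "individual":
        n_term = np.broadcast_to(
            np.asarray(terminal.n, dtype=np.int64), f.shape[1:]
        )
        f_star = rng.binomial(n_term[None, :], f) / n_term[None, :]
    else:
        pool = rng.binomial(terminal.pool_alleles, f) / terminal.pool_alleles
        f_star = rng.binomial(terminal.n, pool) / terminal.n
    delta = np.abs(f_star - p0_obs[None, :])
    return float(delta.mean())


def observed_mean_delta(data: TemporalFreqData, polarize_t0_minor: bool = True) -> float:
    """Observed mean |dp| over sites segregating at t0.

    Frequencies are polarized to the allele that was minor at t0 (the
    absolute difference is invariant to polarization; the flag is kept for
    trajectory reporting symmetry).
    """
    seg = data.segregating_at_t0()
    if not np.any(seg):
        raise ValueError("no segregating sites at t0")
    p0 = data.count_t0[seg] / data.n_t0[seg]
    p1 = data.count_t1[seg] / data.n_t1[seg]
    if polarize_t0_minor:
        flip = p0 > 0.5
        p0 = np.where(flip, 1 - p0, p0)
        p1 = np.where(flip, 1 - p1, p1)
    return float(np.mean(np.abs(p1 - p0)))


def fit_ne(
    data: TemporalFreqData,
    terminal: TerminalDesign,
    seed: int = 0,
    grid_min: int = 1000,
    grid_max: int = 20000,
    grid_step: int = 1000,
    refine_step: int = 100,
    refine_span: int = 5,
    replicates: int = 1000,
    prior_kind: str = "equilibrium",
) -> NeFitResult:
    """Grid search for the haploid N* minimizing |simulated - observed dp|.

    Coarse pass over grid_min..grid_max, then a refinement pass of
    ``refine_span`` steps of ``refine_step`` on either side of the coarse
    optimum. Warns (via ``at_boundary``) when the optimum sits on the grid
    edge, e.g. when observed change is below the sampling noise floor.
    """
    rng = np.random.default_rng(seed)
    seg = data.segregating_at_t0()
    counts = data.count_t0[seg]
    ns = data.n_t0[seg]
    obs = observed_mean_delta(data)
    fgrid = frequency_grid()

    def run(n_star: int) -> float:
        return simulate_fw_delta(
            counts, ns, n_star, data.generations, terminal,
            replicates=replicates,
            seed=np.random.default_rng(rng.integers(2**31)),
            prior_kind=prior_kind, grid=fgrid,
        )

    coarse = np.arange(grid_min, grid_max + 1, grid_step)
    sim = np.array([run(int(n)) for n in coarse])
    best = int(coarse[np.argmin(np.abs(sim - obs))])
    lo = max(1, best - refine_span * refine_step)
    refined = np.arange(lo, best + refine_span * refine_step + 1, refine_step)
    sim_ref = np.array([run(int(n)) for n in refined])
    n_star = int(refined[np.argmin(np.abs(sim_ref - obs))])
    at_boundary = best in (coarse[0], coarse[-1])
    return NeFitResult(
        grid=coarse,
        sim_delta=sim,
        observed_delta=obs,
        refined_grid=refined,
        refined_delta=sim_ref,
        n_star=n_star,
        replicates=replicates,
        at_boundary=at_boundary,
    )


@dataclass
class DemographicHistory:
    """Piecewise-constant diploid sizes ordered from the present backwards.

    ``epochs`` is a list of (duration_in_generations, diploid_size); the
    oldest epoch may have duration ``None`` (open-ended).
    """

    epochs: list
    mu: float = MU_DEFAULT

    def __post_init__(self) -> None:
        for k, (dur, size) in enumerate(self.epochs):
            if size <= 0:
                raise ValueError("epoch size must be positive")
            if dur is not None and dur <= 0:
                raise ValueError("epoch duration must be positive")
            if dur is None and k != len(self.epochs) - 1:
                raise ValueError("only the oldest epoch may be open-ended")


def expected_pairwise_coalescence(history: DemographicHistory) -> float:
    """E[T2] in generations under the piecewise-constant history.

    Within an epoch of diploid size N the pair coalesces at rate 1/(2N);
    integrating the survival function epoch by epoch gives
    E[T2] = sum_k S_k (1 - e^{-lambda_k d_k}) / lambda_k with S_k the
    probability of reaching epoch k without coalescing.
    """
    expect = 0.0
    survival = 1.0
    for dur, size in history.epochs:
        lam = 1.0 / (2.0 * size)
        if dur is None:
            expect += survival / lam
            survival = 0.0
            break
        expect += survival * (1.0 - np.exp(-lam * dur)) / lam
        survival *= np.exp(-lam * dur)
    if survival > 0:  # implicit continuation of the oldest epoch
        lam = 1.0 / (2.0 * history.epochs[-1][1])
        expect += survival / lam
    return float(expect)


def expected_pi_piecewise(history: DemographicHistory) -> float:
    """Expected per-site pi: 2 mu E[T2] (= 4 N mu at equilibrium)."""
    return 2.0 * history.mu * expected_pairwise_coalescence(history)


def sample_pairwise_coalescence(
    history: DemographicHistory,
    n_draws: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Monte-Carlo draws of T2 (independent oracle for the analytic form)."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    remaining = np.ones(n_draws, dtype=bool)
    t = np.zeros(n_draws)
    elapsed = 0.0
    for dur, size in history.epochs:
        lam = 1.0 / (2.0 * size)
        draw = rng.exponential(1.0 / lam, size=n_draws)
        if dur is None:
            t[remaining] = elapsed + draw[remaining]
            remaining[:] = False
            break
        hit = remaining & (draw < dur)
        t[hit] = elapsed + draw[hit]
        remaining &= ~hit
        elapsed += dur
    if remaining.any():
        lam = 1.0 / (2.0 * history.epochs[-1][1])
        t[remaining] = elapsed + rng.exponential(1.0 / lam, size=int(remaining.sum()))
    return t
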
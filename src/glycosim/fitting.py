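"""Rejection ABC with an adaptive score threshold for Golgi-model rates.

The discrepancy between an observed and a simulated profile is

    score = sum_i (sem_i - |obs_i - sim_i|)^2   where |obs_i - sim_i| >= sem_i
            (glycans whose difference is inside the SEM contribute zero)

summed over the union of composition keys; a perfect fit has score 0.
Parameters (one effective rate per enzyme per cisterna, plus optional
quench and input-fraction parameters) are drawn from independent priors:
log-normal for the cisterna where an enzyme predominantly resides,
exponential decay elsewhere.  Proposals whose simulated profile scores at or
below the current threshold are accepted; whenever the acceptance rate in a
sliding window exceeds 7% the threshold is reduced by 10%; once it reaches
the user-defined final threshold, sampling continues at that fixed threshold
until the target number of acceptances, which form the posterior.  Multiple
independent chains are run and checked with the Gelman-Rubin statistic, and
a Mann-Whitney U test flags parameters whose posterior has shifted away from
the prior (candidates for explicit prior re-centering before a re-run).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .simulator import GlycanProfile, GolgiModel, replicate_profile, simulate_profile

__all__ = [
    "Prior",
    "PriorSpec",
    "FitConfig",
    "PosteriorSample",
    "score",
    "sample_prior",
    "abc_rejection",
    "gelman_rubin",
    "prior_shift_test",
    "recenter_prior",
    "posterior_summary",
]

log = logging.getLogger(__name__)

ParameterSet = dict[str, float]


def default_sem(abundance: float) -> float:
    """Fallback SEM for observed entries lacking one: max(0.1%, 5% of value)."""
    return max(0.1, 0.05 * abundance)


def score(
    observed: GlycanProfile,
    simulated: GlycanProfile,
    sem_policy: Optional[Callable[[float], float]] = None,
) -> float:
    """Profile discrepancy; lower is better, 0 when every difference is
    inside the observed SEM.

    Comparison runs over the union of composition keys; a key missing from
    one side contributes abundance 0 there.  Observed keys must carry an SEM
    unless ``sem_policy`` supplies one (keys only present in the simulation
    always use the policy, defaulting to :func:`default_sem`).
    """
    sems = observed.sem or {}
    fallback = sem_policy if sem_policy is not None else default_sem
    if observed.sem is None and sem_policy is None:
        raise ValueError(
            "observed profile has no SEMs; provide them or pass sem_policy"
        )
    total = 0.0
    for key in set(observed.entries) | set(simulated.entries):
        obs = observed.entries.get(key, 0.0)
        sim = simulated.entries.get(key, 0.0)
        if key in sems:
            sem = sems[key]
        elif key in observed.entries and observed.sem is not None:
            raise ValueError(f"observed entry {key!r} has no SEM")
        else:
            sem = fallback(obs)
        diff = abs(obs - sim)
        if diff >= sem:
            total += (sem - diff) ** 2
    return total


@dataclass(frozen=True)
class Prior:
    """Log-normal (median exp(mu), shape sigma) or exponential (mean 1/lam)."""

    dist: str  # "lognormal" | "exponential"
    mu: float = 0.0
    sigma: float = 1.0
    lam: float = 1.0

    def __post_init__(self):
        if self.dist not in ("lognormal", "exponential"):
            raise ValueError(f"unknown prior distribution {self.dist!r}")
        if self.dist == "lognormal" and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.dist == "exponential" and self.lam <= 0:
            raise ValueError("lambda must be > 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "lognormal":
            return float(rng.lognormal(self.mu, self.sigma))
        return float(rng.exponential(1.0 / self.lam))

    def sd(self) -> float:
        if self.dist == "lognormal":
            s2 = self.sigma**2
            return float(math.sqrt((math.exp(s2) - 1) * math.exp(2 * self.mu + s2)))
        return 1.0 / self.lam


PriorSpec = dict[str, Prior]  # parameter name ("ENZ@cisterna") -> prior


def param_name(enzyme: str, cisterna: int) -> str:
    return f"{enzyme}@{cisterna}"


def split_param_name(name: str) -> tuple[str, int]:
    enzyme, _, cisterna = name.rpartition("@")
    return enzyme, int(cisterna)


def sample_prior(priors: PriorSpec, rng: np.random.Generator) -> ParameterSet:
    """Independent draw of every parameter (all positive)."""
    return {name: prior.draw(rng) for name, prior in priors.items()}


def apply_parameters(model: GolgiModel, params: ParameterSet) -> GolgiModel:
    """Model with rate overrides taken from ``params`` (keys "ENZ@c")."""
    overrides = {split_param_name(k): v for k, v in params.items()}
    return model.with_rates(overrides)


@dataclass
class FitConfig:
    acceptance_check_rate: float = 0.07  # shrink when window rate exceeds this
    threshold_shrink: float = 0.10  # multiply threshold by (1 - this)
    target_accepted: int = 10_000  # total acceptances across chains
    final_threshold: Optional[float] = None  # None: pilot quantile
    n_chains: int = 4
    n_glycans_per_sim: int = 10_000
    seed: int = 0
    window: int = 1_000  # sliding window for the acceptance-rate check
    pilot: int = 200  # proposals used to set the initial threshold
    initial_quantile: float = 0.5  # pilot score quantile -> initial threshold
    final_quantile: float = 0.2  # pilot quantile -> final threshold if unset
    max_proposals_per_chain: int = 200_000

    def __post_init__(self):
        if not (0 < self.threshold_shrink < 1):
            raise ValueError("threshold_shrink must be in (0, 1)")
        if not (0 < self.acceptance_check_rate < 1):
            raise ValueError("acceptance_check_rate must be in (0, 1)")
        if self.target_accepted < 1:
            raise ValueError("target_accepted must be >= 1")


@dataclass
class PosteriorSample:
    accepted: list[tuple[ParameterSet, float]]  # fixed-threshold acceptances
    chain_ids: list[int]
    threshold_trajectory: list[list[float]]  # per chain, one entry per shrink
    shrink_phase_accepted: int
    n_proposals: int
    final_threshold: float
    param_names: list[str]
    warnings: list[str] = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array(
            [[p[name] for name in self.param_names] for p, _ in self.accepted]
        )

    def chains(self) -> list[np.ndarray]:
        """Per-chain accepted-parameter arrays (n_accepted, n_params)."""
        arr = self.as_array()
        ids = np.asarray(self.chain_ids)
        return [arr[ids == c] for c in sorted(set(self.chain_ids))]

    def credible_interval(self, name: str, mass: float = 0.9) -> tuple[float, float]:
        j = self.param_names.index(name)
        vals = self.as_array()[:, j]
        lo = (1 - mass) / 2
        return float(np.quantile(vals, lo)), float(np.quantile(vals, 1 - lo))


def _default_simulator(
    observed: GlycanProfile,
    model_template: GolgiModel,
    cfg: FitConfig,
) -> Callable[[ParameterSet, int], GlycanProfile]:
    def simulate(params: ParameterSet, sim_seed: int) -> GlycanProfile:
        model = apply_parameters(model_template, params)
        prof, _ = simulate_profile(
            model, cfg.n_glycans_per_sim, seed=sim_seed, return_events=False
        )
        return prof

    return simulate


def abc_rejection(
    observed: GlycanProfile,
    priors: PriorSpec,
    model_template: Optional[GolgiModel] = None,
    cfg: Optional[FitConfig] = None,
    simulator: Optional[Callable[[ParameterSet, int], GlycanProfile]] = None,
    sem_policy: Optional[Callable[[float], float]] = None,
) -> PosteriorSample:
    """Adaptive-threshold rejection ABC.

    Phases per chain: (1) pilot proposals set the initial (and, if not given,
    final) threshold from score quantiles, shared by all chains; (2) shrink:
    whenever the acceptance rate over the last ``cfg.window`` proposals
    exceeds 7%, the threshold drops by 10% (non-increasing by construction);
    (3) fixed: once at the final threshold, acceptances accumulate until the
    per-chain share of ``target_accepted`` is reached.  Only fixed-phase
    acceptances form the posterior; shrink-phase acceptances are counted but
    logged only.  Non-finite scores reject the proposal with a log entry.
    """
    cfg = cfg or FitConfig()
    if simulator is None:
        if model_template is None:
            raise ValueError("model_template required unless a simulator is given")
        simulator = _default_simulator(observed, model_template, cfg)
    names = sorted(priors)
    ss = np.random.SeedSequence(cfg.seed)
    pilot_ss, *chain_ss = ss.spawn(cfg.n_chains + 1)

    def propose(rng, seed_stream) -> tuple[ParameterSet, float]:
        params = {name: priors[name].draw(rng) for name in names}
        sim_seed = int(seed_stream.integers(0, 2**31 - 1))
        prof = simulator(params, sim_seed)
        return params, score(observed, prof, sem_policy=sem_policy)

    # --- pilot: shared thresholds
    rng = np.random.default_rng(pilot_ss)
    pilot_scores = []
    for _ in range(cfg.pilot):
        _, s = propose(rng, rng)
        if math.isfinite(s):
            pilot_scores.append(s)
    if not pilot_scores:
        raise RuntimeError("all pilot proposals produced non-finite scores")
    initial_threshold = float(np.quantile(pilot_scores, cfg.initial_quantile))
    final_threshold = (
        cfg.final_threshold
        if cfg.final_threshold is not None
        else float(np.quantile(pilot_scores, cfg.final_quantile))
    )
    if final_threshold > initial_threshold:
        initial_threshold = final_threshold

    per_chain_target = max(1, cfg.target_accepted // cfg.n_chains)
    accepted: list[tuple[ParameterSet, float]] = []
    chain_ids: list[int] = []
    trajectory: list[list[float]] = []
    shrink_accepted = 0
    n_proposals = cfg.pilot
    warns: list[str] = []

    for chain, css in enumerate(chain_ss):
        rng = np.random.default_rng(css)
        threshold = initial_threshold
        trajectory.append([])
        window: list[bool] = []
        chain_accepted = 0
        proposals = 0
        while chain_accepted < per_chain_target:
            if proposals >= cfg.max_proposals_per_chain:
                msg = (
                    f"chain {chain}: proposal cap reached with "
                    f"{chain_accepted}/{per_chain_target} acceptances; partial result"
                )
                warnings.warn(msg, RuntimeWarning, stacklevel=2)
                warns.append(msg)
                break
            params, s = propose(rng, rng)
            proposals += 1
            n_proposals += 1
            if not math.isfinite(s):
                log.warning("chain %d: non-finite score, proposal rejected", chain)
                ok = False
            else:
                ok = s <= threshold
            at_final = threshold <= final_threshold
            if ok:
                if at_final:
                    accepted.append((params, s))
                    chain_ids.append(chain)
                    chain_accepted += 1
                else:
                    shrink_accepted += 1
            if not at_final:
                window.append(ok)
                if len(window) > cfg.window:
                    window.pop(0)
                if (
                    len(window) >= cfg.window
                    and sum(window) / len(window) > cfg.acceptance_check_rate
                ):
                    threshold = max(threshold * (1 - cfg.threshold_shrink), final_threshold)
                    trajectory[-1].append(threshold)
    return PosteriorSample(
        accepted=accepted,
        chain_ids=chain_ids,
        threshold_trajectory=trajectory,
        shrink_phase_accepted=shrink_accepted,
        n_proposals=n_proposals,
        final_threshold=final_threshold,
        param_names=names,
        warnings=warns,
    )


def gelman_rubin(chains: list[np.ndarray]) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    ``chains``: m arrays of equal length n (n >= 2), shape (n,) or (n, p).
    R = sqrt(((n-1)/n W + B/n) / W) with W the mean within-chain variance
    and B the between-chain variance of chain means (times n).  Zero
    within-chain variance everywhere gives NaN with a warning.
    """
    arrs = [np.atleast_2d(np.asarray(c, dtype=float).T).T for c in chains]
    if len(arrs) < 2:
        raise ValueError("need at least 2 chains")
    n = arrs[0].shape[0]
    if n < 2 or any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("chains must share a common length >= 2")
    stacked = np.stack(arrs)  # (m, n, p)
    means = stacked.mean(axis=1)  # (m, p)
    variances = stacked.var(axis=1, ddof=1)  # (m, p)
    w = variances.mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    vhat = (n - 1) / n * w + b / n
    r = np.full_like(w, np.nan)
    nonzero = w > 0
    r[nonzero] = np.sqrt(vhat[nonzero] / w[nonzero])
    if not nonzero.all():
        warnings.warn(
            "zero within-chain variance; Gelman-Rubin R undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
    return r


def prior_shift_test(
    prior_draws: np.ndarray,
    posterior_draws: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Two-sided Mann-Whitney U test of prior vs posterior location.

    Returns (p-value, shifted flag).  A flagged parameter is a candidate for
    explicit prior re-centering (see :func:`recenter_prior`) before a re-run;
    re-centering is never applied automatically mid-fit.
    """
    prior_draws = np.asarray(prior_draws)
    posterior_draws = np.asarray(posterior_draws)
    if prior_draws.size == 0 or posterior_draws.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.ptp(prior_draws) == 0 and np.ptp(posterior_draws) == 0 and (
        prior_draws[0] == posterior_draws[0]
    ):
        return 1.0, False
    _, p = stats.mannwhitneyu(prior_draws, posterior_draws, alternative="two-sided")
    return float(p), bool(p < alpha)


def recenter_prior(prior: Prior, posterior_draws: np.ndarray) -> Prior:
    """Re-center a prior on the posterior: a log-normal keeps sigma and moves
    mu to the mean of log(posterior); an exponential sets its mean to the
    posterior mean."""
    posterior_draws = np.asarray(posterior_draws, dtype=float)
    if prior.dist == "lognormal":
        return Prior("lognormal", mu=float(np.mean(np.log(posterior_draws))),
                     sigma=prior.sigma)
    return Prior("exponential", lam=float(1.0 / np.mean(posterior_draws)))


def posterior_summary(
    samples: list[PosteriorSample],
    model_template: GolgiModel,
    n_glycans: int = 10_000,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Mean parameters across fitting runs, their across-run SD, and the
    triplicate profile simulated at the mean parameters.

    Returns (mean ParameterSet, per-parameter SD dict across runs,
    GlycanProfile with SEM).  With a single run the SD is zero.
    """
    if not samples:
        raise ValueError("need at least one fitting run")
    names = samples[0].param_names
    run_means = []
    for s in samples:
        if s.param_names != names:
            raise ValueError("fitting runs disagree on parameter names")
        run_means.append(s.as_array().mean(axis=0))
    run_means = np.array(run_means)
    mean_params = {n: float(v) for n, v in zip(names, run_means.mean(axis=0))}
    sd = run_means.std(axis=0, ddof=1) if len(samples) > 1 else np.zeros(len(names))
    sd_params = {n: float(v) for n, v in zip(names, sd)}
    model = apply_parameters(model_template, mean_params)
    profile = replicate_profile(
        model, n_glycans=n_glycans, n_replicates=n_replicates, seed=seed
    )
    return mean_params, sd_params, profile
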
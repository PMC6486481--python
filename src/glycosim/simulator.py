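"""Gillespie simulation of glycan processing through ordered Golgi cisternae.

A :class:`GolgiModel` is an ordered stack of cisternae with per-cisterna
residence times (default 10 min), a per-(enzyme, cisterna) effective-rate
table (min^-1) and a distribution over the ER-exit input species (default
80% Man8, 15% Man9, 5% Man9Glc).  Each glycan is processed one at a time
with all enzymes present: within a cisterna, reactions are enumerated, a
waiting time is drawn from an exponential with mean 1/total-propensity, and
a reaction is selected with probability propensity/total; when the waiting
time overshoots the residence time the glycan moves to the next cisterna
(no reaction fires at the boundary).  Profiles aggregate the final
structures of many independent glycans by composition key (isoforms
collated), convert to percentages, and drop entries below 0.1% (the
filtered mass is not renormalized).

`simulate_glycan` / `draw_step` form the reference single-glycan path;
`simulate_profile` runs the same process for all glycans on the compiled
state graph (see :mod:`glycosim.engine`) with one independent random
substream per glycan, so output is deterministic in (seed, model, n) and
independent of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import glycans
from .engine import CompiledPathway, compile_pathway, run_batch
from .notation import GlycanStructure, canonicalize, profile_key, serialize
from .rules import (
    ConfigurationError,
    EnzymeRule,
    ReactionInstance,
    ScaleFactorTable,
    apply_rule,
    default_mammalian_rules,
    enumerate_reactions,
)

__all__ = [
    "GolgiModel",
    "GlycanProfile",
    "ReactionEvent",
    "simulate_glycan",
    "draw_step",
    "simulate_profile",
    "replicate_profile",
    "ABUNDANCE_FILTER_PCT",
]

ABUNDANCE_FILTER_PCT = 0.1
DEFAULT_INPUT_DISTRIBUTION = {"Man8": 0.80, "Man9": 0.15, "Man9Glc": 0.05}


@dataclass
class GolgiModel:
    """Ordered cisternae (index 1 = cis) with effective enzyme rates.

    ``rates`` maps (enzyme, cisterna_index) -> effective rate in min^-1;
    missing pairs mean the enzyme is absent from that cisterna.
    """

    n_cisternae: int
    residence_times: list[float]  # minutes, one per cisterna
    rates: dict[tuple[str, int], float]
    input_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INPUT_DISTRIBUTION)
    )
    rules: Optional[list[EnzymeRule]] = None
    scale_factors: Optional[ScaleFactorTable] = None

    def __post_init__(self):
        if self.n_cisternae < 1:
            raise ConfigurationError("need at least one cisterna")
        if len(self.residence_times) != self.n_cisternae:
            raise ConfigurationError("one residence time per cisterna required")
        if any(t <= 0 for t in self.residence_times):
            raise ConfigurationError("residence times must be positive")
        for (enzyme, cisterna), rate in self.rates.items():
            if not (1 <= cisterna <= self.n_cisternae):
                raise ConfigurationError(
                    f"rate for {enzyme}@{cisterna}: cisterna out of range"
                )
            if rate < 0:
                raise ConfigurationError(f"negative rate for {enzyme}@{cisterna}")
        total = sum(self.input_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"input distribution must sum to 1 (got {total})"
            )
        if (self.rules is None) != (self.scale_factors is None):
            raise ConfigurationError("rules and scale_factors must be set together")

    def ruleset(self) -> tuple[list[EnzymeRule], ScaleFactorTable]:
        if self.rules is None:
            return default_mammalian_rules()
        return self.rules, self.scale_factors

    def cisterna_rates(self, cisterna: int) -> dict[str, float]:
        return {e: r for (e, c), r in self.rates.items() if c == cisterna}

    def with_rates(self, overrides: dict[tuple[str, int], float]) -> "GolgiModel":
        new = dict(self.rates)
        new.update(overrides)
        return GolgiModel(
            self.n_cisternae,
            list(self.residence_times),
            new,
            dict(self.input_distribution),
            self.rules,
            self.scale_factors,
        )

    def scaled(self, multipliers: dict[str, float]) -> "GolgiModel":
        """Scale every cisternal rate of the named enzymes."""
        enzymes_present = {e for e, _ in self.rates}
        unknown = set(multipliers) - enzymes_present
        if unknown:
            raise ConfigurationError(f"unknown enzymes: {sorted(unknown)}")
        new = {
            (e, c): r * multipliers.get(e, 1.0) for (e, c), r in self.rates.items()
        }
        return GolgiModel(
            self.n_cisternae,
            list(self.residence_times),
            new,
            dict(self.input_distribution),
            self.rules,
            self.scale_factors,
        )


@dataclass
class GlycanProfile:
    """Relative abundances (%) keyed by composition, with optional SEM (%)."""

    entries: dict[str, float]
    sem: Optional[dict[str, float]] = None

    def total(self) -> float:
        return sum(self.entries.values())

    def filtered(self, threshold: float = ABUNDANCE_FILTER_PCT) -> "GlycanProfile":
        """Drop entries below ``threshold`` percent; no renormalization."""
        keep = {k: v for k, v in self.entries.items() if v >= threshold}
        sem = (
            {k: self.sem[k] for k in keep if k in self.sem}
            if self.sem is not None
            else None
        )
        return GlycanProfile(keep, sem)


@dataclass(frozen=True)
class ReactionEvent:
    glycan_index: int
    cisterna: int  # 1-based
    time: float  # minutes within the cisterna
    enzyme: str
    substrate_key: str
    product_key: str
    substrate: str  # serialized structures
    product: str


def draw_step(
    reactions: list[ReactionInstance],
    clock: float,
    residence_time: float,
    rng: np.random.Generator,
) -> tuple[Optional[ReactionInstance], float]:
    """One SSA step: returns (chosen reaction or None for cisterna exit, dt).

    P(reaction i) = r_i / R with R the total propensity; dt is exponential
    with mean 1/R.  Exit when R == 0 or the step overshoots the residence
    time (the overshooting dt is discarded: no reaction fires).
    """
    total = sum(r.propensity for r in reactions)
    if total <= 0:
        return None, residence_time - clock
    dt = rng.exponential(1.0 / total)
    if clock + dt >= residence_time:
        return None, residence_time - clock
    u = rng.random() * total
    acc = 0.0
    for r in reactions:
        acc += r.propensity
        if u <= acc:
            return r, dt
    return reactions[-1], dt  # numerical edge: u == total


def simulate_glycan(
    g0: GlycanStructure,
    model: GolgiModel,
    rng: np.random.Generator,
    glycan_index: int = 0,
) -> tuple[GlycanStructure, list[ReactionEvent]]:
    """Reference single-glycan SSA over explicit structures.

    The within-cisterna clock resets at each cisterna entry; the quenched
    flag is absorbing across cisternae.
    """
    rules, table = model.ruleset()
    g = canonicalize(g0)
    events: list[ReactionEvent] = []
    for cisterna in range(1, model.n_cisternae + 1):
        rates = model.cisterna_rates(cisterna)
        clock = 0.0
        limit = model.residence_times[cisterna - 1]
        while True:
            reactions = enumerate_reactions(g, rules, table, rates)
            chosen, dt = draw_step(reactions, clock, limit, rng)
            if chosen is None:
                break
            clock += dt
            product = apply_rule(chosen.rule, g, chosen.site)
            events.append(
                ReactionEvent(
                    glycan_index=glycan_index,
                    cisterna=cisterna,
                    time=clock,
                    enzyme=chosen.rule.enzyme,
                    substrate_key=profile_key(g),
                    product_key=profile_key(product),
                    substrate=serialize(g),
                    product=serialize(product),
                )
            )
            g = product
    return g, events


def _resolve_species(name: str) -> GlycanStructure:
    """Input-distribution keys: ER-exit names (Man8/Man9/Man9Glc) or
    explicit linear-notation strings."""
    try:
        return glycans.er_exit_structure(name)
    except KeyError:
        from .notation import parse_linear

        return parse_linear(name)


def _compiled_for(model: GolgiModel) -> CompiledPathway:
    rules, table = model.ruleset()
    seeds = {name: _resolve_species(name) for name in model.input_distribution}
    return compile_pathway(rules, table, seeds)


def _glycan_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


def _simulate_final_states(model: GolgiModel, n_glycans: int, seed: int):
    """Run the batch kernel; returns (compiled, final_states, event arrays).

    Input species are drawn from a dedicated substream of ``seed``; each
    glycan's trajectory runs on its own substream.
    """
    if n_glycans < 1:
        raise ValueError("n_glycans must be >= 1")
    compiled = _compiled_for(model)
    rate_matrix = compiled.rate_matrix(model.rates, model.n_cisternae)
    residence = np.asarray(model.residence_times, dtype=np.float64)

    input_ss, _ = np.random.SeedSequence(seed).spawn(2)
    names = sorted(model.input_distribution)
    fractions = np.array([model.input_distribution[n] for n in names])
    start_choices = np.array([compiled.start_index[n] for n in names], dtype=np.int64)
    picks = np.random.default_rng(input_ss).choice(
        len(names), size=n_glycans, p=fractions / fractions.sum()
    )
    start_states = start_choices[picks]
    seeds = _glycan_seeds(seed, n_glycans)
    final, ev_g, ev_c, ev_t, ev_e = run_batch(
        compiled, rate_matrix, residence, start_states, seeds
    )
    return compiled, final, (ev_g, ev_c, ev_t, ev_e)


def simulate_profile(
    model: GolgiModel,
    n_glycans: int = 10_000,
    seed: int = 0,
    min_abundance: float = ABUNDANCE_FILTER_PCT,
    return_events: bool = True,
):
    """Simulate ``n_glycans`` independent glycans and aggregate the profile.

    Returns ``(GlycanProfile, FluxMap)``; the flux map carries the full
    event log (``flux_map.events`` DataFrame).  Isoforms are collated by
    composition key; abundances below ``min_abundance`` percent are removed
    without renormalization (set 0 to keep everything).
    """
    from .flux import build_flux_map  # avoid import cycle

    compiled, final, (ev_g, ev_c, ev_t, ev_e) = _simulate_final_states(
        model, n_glycans, seed
    )

    counts: dict[str, int] = {}
    for s in final:
        key = compiled.state_profile_keys[s]
        counts[key] = counts.get(key, 0) + 1
    entries = {k: 100.0 * c / n_glycans for k, c in sorted(counts.items())}
    profile = GlycanProfile(entries)
    if min_abundance > 0:
        profile = profile.filtered(min_abundance)

    events = _events_dataframe(compiled, ev_g, ev_c, ev_t, ev_e) if return_events else None
    flux_map = build_flux_map(events, profile) if return_events else None
    return profile, flux_map


def _events_dataframe(compiled, ev_g, ev_c, ev_t, ev_e) -> pd.DataFrame:
    # substrate state of edge j: the state whose CSR slice contains j
    sub_state = np.searchsorted(compiled.indptr, ev_e, side="right") - 1
    prod_state = compiled.edge_next[ev_e]
    enz = np.asarray(compiled.enzymes)[compiled.edge_enzyme[ev_e]]
    keys = np.asarray(compiled.state_profile_keys)
    strs = np.asarray(compiled.state_keys)
    return pd.DataFrame(
        {
            "glycan_index": ev_g,
            "cisterna": ev_c + 1,
            "time": ev_t,
            "enzyme": enz,
            "substrate_key": keys[sub_state],
            "product_key": keys[prod_state],
            "substrate": strs[sub_state],
            "product": strs[prod_state],
        }
    )


def replicate_profile(
    model: GolgiModel,
    n_glycans: int = 10_000,
    n_replicates: int = 3,
    seed: int = 0,
    min_abundance: float = ABUNDANCE_FILTER_PCT,
) -> GlycanProfile:
    """Mean profile with SEM over independent replicate simulations.

    Per key: mean abundance and SEM = sd/sqrt(n) across replicates (keys
    absent from a replicate contribute 0).  The abundance filter is applied
    to the mean profile after averaging.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for an SEM")
    rep_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    reps = []
    for rs in rep_seeds:
        sub_seed = int(rs.generate_state(1, dtype=np.uint32)[0])
        prof, _ = simulate_profile(
            model, n_glycans, seed=sub_seed, min_abundance=0.0, return_events=False
        )
        reps.append(prof.entries)
    keys = sorted(set().union(*reps))
    entries, sem = {}, {}
    for k in keys:
        vals = np.array([r.get(k, 0.0) for r in reps])
        entries[k] = float(vals.mean())
        sem[k] = float(vals.std(ddof=1) / math.sqrt(n_replicates))
    profile = GlycanProfile(entries, sem)
    if min_abundance > 0:
        profile = profile.filtered(min_abundance)
    return profile
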
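"""Synthetic ground-truth scenarios and observed-profile generation.

Stands in for experimental triplicate MALDI profiles: a scenario bundles a
known ground-truth :class:`GolgiModel`, replicate settings and an optional
enzyme-level perturbation (rate multipliers; 0 is a knockout).  Shipped
presets cover the regimes of interest — an oligomannose-dominated
3-cisterna model, a complex-glycan 4-cisterna model, its mannosidase-II
knockout (swainsonine-like) and a COG-disruption-like knockdown, plus a
reduced 5-enzyme fitting scenario — with ground-truth rates frozen in
version-controlled preset files.  Replicate noise comes solely from the
finite number of simulated glycans; an optional multiplicative
measurement-noise knob exists but defaults to off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .fitting import Prior, PriorSpec
from .simulator import GlycanProfile, GolgiModel, replicate_profile

__all__ = ["SyntheticScenario", "PRESETS", "make_scenario", "synth_observed", "perturb"]

PRESETS = ("oligomannose-3c", "complex-4c", "man2-null", "cog4-like", "fit-demo-3c")


@dataclass
class SyntheticScenario:
    name: str
    ground_truth: GolgiModel
    n_replicates: int
    n_glycans: int
    seed: int
    perturbation: dict[str, float] = field(default_factory=dict)
    priors: Optional[PriorSpec] = None

    def __post_init__(self):
        if any(m < 0 for m in self.perturbation.values()):
            raise ValueError("perturbation multipliers must be >= 0")

    def model(self) -> GolgiModel:
        """Ground truth with the perturbation applied."""
        if not self.perturbation:
            return self.ground_truth
        return self.ground_truth.scaled(self.perturbation)


def _load_preset(name: str) -> dict:
    path = resources.files("glycosim.data.presets").joinpath(f"{name}.yaml")
    try:
        return yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def _model_from_config(cfg: dict) -> GolgiModel:
    rates = {
        (enzyme, int(c)): float(r)
        for enzyme, by_cist in cfg["rates"].items()
        for c, r in by_cist.items()
    }
    return GolgiModel(
        n_cisternae=int(cfg["n_cisternae"]),
        residence_times=[float(t) for t in cfg["residence_times"]],
        rates=rates,
        input_distribution={k: float(v) for k, v in cfg["input_distribution"].items()},
    )


def _priors_from_config(cfg: dict) -> PriorSpec:
    out: PriorSpec = {}
    for name, spec in cfg.items():
        if spec["dist"] == "lognormal":
            out[name] = Prior("lognormal", mu=float(spec["mu"]), sigma=float(spec["sigma"]))
        else:
            out[name] = Prior("exponential", lam=float(spec["lam"]))
    return out


def make_scenario(preset: str, seed: int = 0) -> SyntheticScenario:
    """Fully specified scenario for a named preset; a pure function of
    (preset, seed)."""
    cfg = _load_preset(preset)
    perturbation = {k: float(v) for k, v in cfg.get("perturbation", {}).items()}
    if "base" in cfg:
        base = _load_preset(cfg["base"])
        model_cfg, meta = base["model"], base
    else:
        model_cfg, meta = cfg["model"], cfg
    priors = _priors_from_config(meta["priors"]) if "priors" in meta else None
    return SyntheticScenario(
        name=cfg["name"],
        ground_truth=_model_from_config(model_cfg),
        n_replicates=int(meta.get("n_replicates", 3)),
        n_glycans=int(meta.get("n_glycans", 10_000)),
        seed=seed,
        perturbation=perturbation,
        priors=priors,
    )


def synth_observed(
    scenario: SyntheticScenario,
    measurement_noise_cv: float = 0.0,
) -> GlycanProfile:
    """Triplicate-style observed profile with per-key SEM, simulated from
    the scenario's (perturbed) ground truth.

    ``measurement_noise_cv`` > 0 adds optional multiplicative log-normal
    measurement noise per key on top of the sampling noise (off by default:
    the model's own finite-sample stochasticity is the noise source).
    """
    profile = replicate_profile(
        scenario.model(),
        n_glycans=scenario.n_glycans,
        n_replicates=scenario.n_replicates,
        seed=scenario.seed,
    )
    if measurement_noise_cv > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(scenario.seed).spawn(3)[2]
        )
        sigma = float(np.sqrt(np.log1p(measurement_noise_cv**2)))
        noisy = {
            k: v * rng.lognormal(-(sigma**2) / 2, sigma)
            for k, v in profile.entries.items()
        }
        profile = GlycanProfile(noisy, profile.sem)
    return profile


def perturb(scenario: SyntheticScenario, multipliers: dict[str, float]) -> SyntheticScenario:
    """New scenario with additional per-enzyme rate multipliers (applied on
    top of any existing perturbation); unknown enzymes are an error."""
    known = {e for e, _ in scenario.ground_truth.rates}
    unknown = set(multipliers) - known
    if unknown:
        raise KeyError(f"unknown enzymes: {sorted(unknown)}")
    combined = dict(scenario.perturbation)
    for enzyme, mult in multipliers.items():
        combined[enzyme] = combined.get(enzyme, 1.0) * mult
    return SyntheticScenario(
        name=scenario.name,
        ground_truth=scenario.ground_truth,
        n_replicates=scenario.n_replicates,
        n_glycans=scenario.n_glycans,
        seed=scenario.seed,
        perturbation=combined,
        priors=scenario.priors,
    )
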
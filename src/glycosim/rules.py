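"""Enzyme reaction rules: substrate patterns, substitutions, scale factors.

Each enzyme is a rule that matches residues ("sites") inside a glycan tree
and performs a substitution there: add a residue at a linkage, remove the
matched residue (or the matched terminal unit, for endo-mannosidase), or set
the quenched flag (the oligomannose-quench pseudo-enzyme).  Context-specific
substrate preferences are modeled as scale factors that multiply the
cisternal effective rate when a whole-glycan predicate holds, e.g. the
slower Man6 -> Man5 trimming step of MAN1 or the reduced FUT8 rate on
Man5-bearing substrates.

Rules are declarative: a residue-level ``match`` dict plus a whole-glycan
``guards`` dict, evaluated by :func:`match_sites`.  The shipped default rule
set (``data/rules_default.yaml``) is a documented mammalian pathway
reconstruction: MAN1 stepwise alpha-1,2 trimming, endo-mannosidase, MGAT1/2/4/5
antenna initiation, MAN2 hybrid->complex conversion, GalT, arm-specific
sialyltransferases, FUT8 core fucosylation, grouped antenna
fucosyltransferases, and the OM-quench pseudo-enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from . import notation
from .notation import (
    GlycanClass,
    GlycanStructure,
    anatomy,
    antenna_count,
    canonicalize,
    classify,
    count_sugar,
)

__all__ = [
    "EnzymeRule",
    "ScaleFactor",
    "ScaleFactorTable",
    "ReactionInstance",
    "ConfigurationError",
    "default_mammalian_rules",
    "load_rules",
    "rules_fingerprint",
    "match_sites",
    "apply_rule",
    "enumerate_reactions",
]

Site = tuple[int, ...]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class EnzymeRule:
    """One enzymatic substitution: where it can act and what it does."""

    enzyme: str
    match: dict
    action: dict
    guards: dict = field(default_factory=dict)
    scale_factor_id: Optional[str] = None

    def __post_init__(self):
        kinds = [k for k in ("add", "remove", "remove_subtree", "quench") if k in self.action]
        if len(kinds) != 1:
            raise ConfigurationError(
                f"rule for {self.enzyme}: action must be exactly one of "
                f"add/remove/remove_subtree/quench, got {self.action}"
            )


@dataclass(frozen=True)
class ScaleFactor:
    id: str
    enzyme: str
    when: dict  # whole-glycan guard predicate
    factor: float

    def __post_init__(self):
        if self.factor <= 0:
            raise ConfigurationError(f"scale factor {self.id}: multiplier must be > 0")


@dataclass
class ScaleFactorTable:
    entries: list[ScaleFactor] = field(default_factory=list)

    def lookup(self, enzyme: str, g: GlycanStructure) -> float:
        """First matching entry's multiplier, else 1.0."""
        for e in self.entries:
            if e.enzyme == enzyme and _eval_guards(g, e.when):
                return e.factor
        return 1.0


@dataclass(frozen=True)
class ReactionInstance:
    rule: EnzymeRule
    site: Site
    propensity: float  # cisternal effective rate x scale factor, min^-1


# ---------------------------------------------------------------------------
# predicate evaluation


def _eval_count(value, spec) -> bool:
    if isinstance(spec, dict):
        if "min" in spec and value < spec["min"]:
            return False
        if "max" in spec and value > spec["max"]:
            return False
        return True
    return value == spec


def _eval_guards(g: GlycanStructure, guards: dict) -> bool:
    for key, spec in guards.items():
        if key == "man_count":
            if not _eval_count(count_sugar(g, "Man"), spec):
                return False
        elif key == "glc_count":
            if not _eval_count(count_sugar(g, "Glc"), spec):
                return False
        elif key == "antenna_count":
            if not _eval_count(antenna_count(g), spec):
                return False
        elif key == "glycan_class":
            if classify(g) is not GlycanClass(spec):
                return False
        elif key == "has_core_fucose":
            a = anatomy(g)
            has = any(c.sugar == "Fuc" for _, c in a.root.children)
            if has != bool(spec):
                return False
        else:
            raise ConfigurationError(f"unknown guard {key!r}")
    return True


class _Context:
    """Precomputed structural roles for one (canonical) glycan."""

    def __init__(self, g: GlycanStructure):
        self.g = g
        a = anatomy(g)
        self.roles: dict[int, str] = {id(g): "root"}
        if a.core_man is not None:
            self.roles[id(a.core_man)] = "core_man"
        if a.arm3 is not None:
            self.roles[id(a.arm3)] = "arm3_man"
        if a.arm6 is not None:
            self.roles[id(a.arm6)] = "arm6_man"
        # arm membership ("3" / "6") for every residue under a core arm
        self.arm: dict[int, str] = {}
        for arm_node, label in ((a.arm3, "3"), (a.arm6, "6")):
            if arm_node is not None:
                for node in arm_node.walk():
                    self.arm[id(node)] = label
        self.antenna_glcnacs = {id(n) for n in notation._antennae(g)}


def _match_residue(
    ctx: _Context,
    node: GlycanStructure,
    linkage: str,
    parent: Optional[GlycanStructure],
    match: dict,
) -> bool:
    for key, spec in match.items():
        if key == "sugar":
            if node.sugar != spec:
                return False
        elif key == "linkage":
            allowed = spec if isinstance(spec, list) else [spec]
            if linkage not in allowed:
                return False
        elif key == "leaf":
            if bool(node.children) == bool(spec):
                return False
        elif key == "role":
            if ctx.roles.get(id(node)) != spec:
                return False
        elif key == "parent_role":
            if parent is None or ctx.roles.get(id(parent)) != spec:
                return False
        elif key == "arm":
            if ctx.arm.get(id(node)) != spec:
                return False
        elif key == "is_antenna_glcnac":
            if (id(node) in ctx.antenna_glcnacs) != bool(spec):
                return False
        elif key == "parent_is_antenna_glcnac":
            if parent is None or (id(parent) in ctx.antenna_glcnacs) != bool(spec):
                return False
        elif key == "lacks_child_sugar":
            lacking = spec if isinstance(spec, list) else [spec]
            if any(c.sugar in lacking for _, c in node.children):
                return False
        elif key == "lacks_child_linkage":
            if any(lk == spec for lk, _ in node.children):
                return False
        elif key in ("has_child", "has_bare_child"):
            want_sugar = spec.get("sugar")
            want_link = spec.get("linkage")
            bare = key == "has_bare_child"  # child must itself be unsubstituted
            ok = any(
                (want_sugar is None or c.sugar == want_sugar)
                and (want_link is None or lk == want_link)
                and (not bare or not c.children)
                for lk, c in node.children
            )
            if not ok:
                return False
        elif key == "only_child":
            if len(node.children) != 1:
                return False
            _, child = node.children[0]
            if child.sugar != spec.get("sugar", child.sugar):
                return False
        elif key == "subtree_lacks":
            lacking = spec if isinstance(spec, list) else [spec]
            if any(n.sugar in lacking for n in node.walk() if n is not node):
                return False
        else:
            raise ConfigurationError(f"unknown match field {key!r}")
    return True


def match_sites(rule: EnzymeRule, g: GlycanStructure) -> list[Site]:
    """All sites (paths of child indices in the canonical tree) where the
    rule can act.  A quenched glycan matches nothing.  Deterministic order:
    depth-first over the canonical tree."""
    g = canonicalize(g)
    if g.quenched:
        return []
    if not _eval_guards(g, rule.guards):
        return []
    ctx = _Context(g)
    sites: list[Site] = []

    def visit(node: GlycanStructure, linkage: str, parent, path: Site):
        if _match_residue(ctx, node, linkage, parent, rule.match):
            sites.append(path)
        for idx, (lk, child) in enumerate(node.children):
            visit(child, lk, node, path + (idx,))

    visit(g, "", None, ())
    return sites


def _node_at(g: GlycanStructure, site: Site) -> GlycanStructure:
    node = g
    for idx in site:
        node = node.children[idx][1]
    return node


def apply_rule(rule: EnzymeRule, g: GlycanStructure, site: Site) -> GlycanStructure:
    """Apply the rule at ``site`` (a path valid in the canonical form of
    ``g``); returns a new canonical structure, the input is unmodified."""
    canon = canonicalize(g)
    if site not in match_sites(rule, canon):
        raise ValueError(f"site {site} does not match rule {rule.enzyme}")
    new = canon.copy()
    if "quench" in rule.action:
        new.quenched = True
        return canonicalize(new)
    if "add" in rule.action:
        spec = rule.action["add"]
        target = _node_at(new, site)
        target.children.append((spec["linkage"], GlycanStructure(spec["sugar"])))
        return canonicalize(new)
    # remove / remove_subtree: detach the residue at `site` from its parent
    if not site:
        raise ValueError("cannot remove the root residue")
    parent = _node_at(new, site[:-1])
    removed = parent.children.pop(site[-1])[1]
    if "remove" in rule.action and removed.children:
        raise ValueError(
            f"rule {rule.enzyme}: 'remove' matched a non-terminal residue"
        )
    return canonicalize(new)


def enumerate_reactions(
    g: GlycanStructure,
    rules: list[EnzymeRule],
    scale_factors: ScaleFactorTable,
    cisterna_rates: dict[str, float],
) -> list[ReactionInstance]:
    """One :class:`ReactionInstance` per (rule, site) pair for every enzyme
    present in ``cisterna_rates``; propensity = cisternal rate x scale factor.

    Rate-map keys that name no rule are a configuration error; rule enzymes
    absent from the map are treated as rate zero (enzyme not in this
    cisterna) and produce no instances.
    """
    known = {r.enzyme for r in rules}
    unknown = set(cisterna_rates) - known
    if unknown:
        raise ConfigurationError(f"rates given for unknown enzymes: {sorted(unknown)}")
    canon = canonicalize(g)
    out: list[ReactionInstance] = []
    for rule in rules:
        rate = cisterna_rates.get(rule.enzyme)
        if rate is None:
            continue
        if rate < 0:
            raise ConfigurationError(f"negative rate for {rule.enzyme}")
        sites = match_sites(rule, canon)
        if not sites:
            continue
        scale = scale_factors.lookup(rule.enzyme, canon)
        for site in sites:
            out.append(ReactionInstance(rule, site, rate * scale))
    return out


# ---------------------------------------------------------------------------
# default rule set


def _parse_rules_config(cfg: dict) -> tuple[list[EnzymeRule], ScaleFactorTable]:
    table = ScaleFactorTable(
        [
            ScaleFactor(
                id=e["id"], enzyme=e["enzyme"], when=e.get("when", {}), factor=float(e["factor"])
            )
            for e in cfg.get("scale_factors", [])
        ]
    )
    rules = []
    for r in cfg["rules"]:
        rules.append(
            EnzymeRule(
                enzyme=r["enzyme"],
                match=r.get("match", {}),
                action=r["action"],
                guards=r.get("guards", {}),
                scale_factor_id=r.get("scale_factor_id"),
            )
        )
    return rules, table


def load_rules(path_or_stream) -> tuple[list[EnzymeRule], ScaleFactorTable]:
    """Load a rules configuration file (YAML)."""
    if hasattr(path_or_stream, "read"):
        cfg = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            cfg = yaml.safe_load(fh)
    return _parse_rules_config(cfg)


def default_mammalian_rules() -> tuple[list[EnzymeRule], ScaleFactorTable]:
    """The shipped default mammalian N-glycosylation rule set."""
    text = resources.files("glycosim.data").joinpath("rules_default.yaml").read_text()
    return _parse_rules_config(yaml.safe_load(text))


def rules_fingerprint(rules: list[EnzymeRule], table: ScaleFactorTable) -> str:
    """Stable identity string for a rule set (used to cache compiled pathways)."""
    import hashlib

    blob = repr([(r.enzyme, sorted(r.match.items()), sorted(r.action.items()),
                  sorted(r.guards.items()), r.scale_factor_id) for r in rules])
    blob += repr([(e.id, e.enzyme, sorted(e.when.items()), e.factor) for e in table.entries])
    return hashlib.sha256(blob.encode()).hexdigest()
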
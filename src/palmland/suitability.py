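"""Decision-rule land-suitability classification for oil palm.

Land on tropical floodplains is commercially redundant for oil palm where
periodic inundation kills palms: low-lying cells near the river channel, and
lower-lying depressions further from it.  Suitability is expressed as an
ordered :class:`RuleSet` of interval conjunctions over three biophysical
predictors — Euclidean distance to the main river (m), elevation (m ASL) and
an ordinal soil agricultural-suitability class (1 = unsuitable, 2 = marginal,
3 = suitable, 4 = very suitable).  Every rule maps to the ``redundant``
class; points matching no rule fall through to the ``full_stand`` default,
so evaluation is exhaustive and deterministic (first match wins, though the
printed rules are non-conflicting).

The reference rule set encodes the three thresholds identified by a CART
analysis of productive versus grossly underproductive plantation blocks in a
Southeast-Asian floodplain study region; :mod:`palmland.cart` re-induces
comparable trees from training samples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid

__all__ = [
    "FULL_STAND",
    "REDUNDANT",
    "SUITABILITY_CODES",
    "Condition",
    "Rule",
    "RuleSet",
    "reference_ruleset",
    "classify_points",
    "classify_raster",
]

FULL_STAND = "full_stand"
REDUNDANT = "redundant"

#: Integer raster codes for suitability maps: 0 = full_stand/suitable,
#: 1 = redundant/unsuitable.
SUITABILITY_CODES = {FULL_STAND: 0, REDUNDANT: 1}

#: Predictor names in declaration order (also the CART tie-break order).
PREDICTORS = ("dist_river", "elevation", "soil")


@dataclass(frozen=True)
class Condition:
    """An interval condition ``low < var <= high`` with optional closed ends."""

    var: str
    low: float = -math.inf
    high: float = math.inf
    include_low: bool = False
    include_high: bool = True

    def matches(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = (x >= self.low) if self.include_low else (x > self.low)
        hi = (x <= self.high) if self.include_high else (x < self.high)
        return lo & hi

    def to_dict(self) -> dict:
        d = {"var": self.var}
        if self.low != -math.inf:
            d["low"] = self.low
            d["include_low"] = self.include_low
        if self.high != math.inf:
            d["high"] = self.high
            d["include_high"] = self.include_high
        return d

    def describe(self) -> str:
        parts = []
        if self.low != -math.inf:
            parts.append(f"{self.low} {'<=' if self.include_low else '<'}")
        parts.append(self.var)
        if self.high != math.inf:
            parts.append(f"{'<=' if self.include_high else '<'} {self.high}")
        return " ".join(parts)


@dataclass(frozen=True)
class Rule:
    """A conjunction of conditions mapping to a class label."""

    conditions: tuple[Condition, ...]
    label: str

    def matches(self, **vars: np.ndarray) -> np.ndarray:
        out = None
        for cond in self.conditions:
            m = cond.matches(vars[cond.var])
            out = m if out is None else (out & m)
        if out is None:  # unconditional rule
            shapes = [np.asarray(v).shape for v in vars.values()]
            out = np.ones(shapes[0] if shapes else (), dtype=bool)
        return out

    def describe(self) -> str:
        body = " AND ".join(c.describe() for c in self.conditions) or "TRUE"
        return f"IF {body} THEN {self.label}"


@dataclass
class RuleSet:
    """Ordered rules with a default class; first matching rule wins."""

    rules: tuple[Rule, ...]
    default: str = FULL_STAND

    def classify(self, **vars: np.ndarray) -> np.ndarray:
        """Vectorised classification; returns an object array of labels."""
        arrays = {k: np.asarray(v, dtype=float) for k, v in vars.items()}
        shape = next(iter(arrays.values())).shape
        out = np.full(shape, self.default, dtype=object)
        unassigned = np.ones(shape, dtype=bool)
        for rule in self.rules:
            hit = rule.matches(**arrays) & unassigned
            out[hit] = rule.label
            unassigned &= ~hit
        return out

    def classify_one(self, dist_river: float, elevation: float, soil: float) -> str:
        return self.classify(
            dist_river=np.array([dist_river]),
            elevation=np.array([elevation]),
            soil=np.array([soil]),
        )[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "default": self.default,
                "rules": [
                    {"label": r.label, "conditions": [c.to_dict() for c in r.conditions]}
                    for r in self.rules
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        obj = json.loads(text)
        rules = tuple(
            Rule(
                conditions=tuple(
                    Condition(
                        var=c["var"],
                        low=c.get("low", -math.inf),
                        high=c.get("high", math.inf),
                        include_low=c.get("include_low", False),
                        include_high=c.get("include_high", True),
                    )
                    for c in r["conditions"]
                ),
                label=r["label"],
            )
            for r in obj["rules"]
        )
        return cls(rules=rules, default=obj["default"])

    def describe(self) -> str:
        lines = [r.describe() for r in self.rules]
        lines.append(f"ELSE {self.default}")
        return "\n".join(lines)


def reference_ruleset() -> RuleSet:
    """The three floodplain suitability rules for commercially redundant land.

    1. within 1,504 m of the river and at most 22.4 m ASL;
    2. beyond 1,504 m, at most 16 m ASL, on marginal soil (class 2);
    3. beyond 1,947 m, on very suitable soil (class 4), 9.9–14 m ASL.

    Anything else is classed as full-stand (suitable).  Rules 2 and 3 pick
    out lower-lying depressions prone to periodic flooding or waterlogging.
    """
    r1 = Rule(
        conditions=(
            Condition("dist_river", high=1504.0),
            Condition("elevation", high=22.4),
        ),
        label=REDUNDANT,
    )
    r2 = Rule(
        conditions=(
            Condition("dist_river", low=1504.0),
            Condition("elevation", high=16.0),
            Condition("soil", low=1.5, high=2.5),
        ),
        label=REDUNDANT,
    )
    r3 = Rule(
        conditions=(
            Condition("dist_river", low=1947.0),
            Condition("soil", low=3.5, high=4.5),
            Condition("elevation", low=9.9, high=14.0, include_low=True),
        ),
        label=REDUNDANT,
    )
    return RuleSet(rules=(r1, r2, r3), default=FULL_STAND)


def classify_points(rules: RuleSet, dist_river, elevation, soil) -> np.ndarray:
    """Classify arrays of points; returns label array."""
    return rules.classify(
        dist_river=np.asarray(dist_river),
        elevation=np.asarray(elevation),
        soil=np.asarray(soil),
    )


def classify_raster(stack, rules: RuleSet) -> RasterGrid:
    """Cell-wise rule classification of a landscape stack.

    Returns an integer-coded suitability grid (0 = full_stand, 1 = redundant);
    nodata in any predictor layer propagates to the output.

    Raises
    ------
    ValueError
        Naming the missing layer if the stack lacks a required predictor.
    """
    for name in ("dist_river", "elevation", "soil"):
        if getattr(stack, name, None) is None:
            raise ValueError(f"stack is missing required layer: {name}")
    dist, elev, soil = stack.dist_river, stack.elevation, stack.soil
    for layer in (elev, soil):
        if not dist.aligned_with(layer):
            raise ValueError("stack layers are not mutually aligned")

    labels = rules.classify(
        dist_river=dist.values, elevation=elev.values, soil=soil.values
    )
    codes = np.where(labels == REDUNDANT, 1, 0).astype(np.int64)
    valid = dist.mask() & elev.mask() & soil.mask()
    nodata = int(dist.nodata)
    codes[~valid] = nodata
    return dist.copy_with(codes, nodata=nodata, categories=(0, 1))
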
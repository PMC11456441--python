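"""Consensus deleteriousness scoring across 12 in-silico predictors.

Each predictor's raw output (a categorical code such as SIFT's ``D``/``T``
or a numeric score such as CADD's PHRED value) is mapped to one of three
levels: deleterious (D), probably deleterious (P) or tolerable (T).  The
per-variant tallies nD, nP, nT over the registered tools feed the HARM
consensus statistic

    HARM = nD + 0.4 * nP - nT

and two decision criteria: (1) nD > 0 — at least one tool calls the variant
outright deleterious; (2) HARM > 0 — weighted support outweighs tolerance.
A variant is called deleterious under a configurable combination rule
(default: both criteria).

Missing predictions count toward none of the tallies: absence of evidence
is not tolerance, and nT enters the statistic with a negative sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import yaml

__all__ = [
    "HARM_P_WEIGHT",
    "ToolCriterion",
    "ToolRegistry",
    "ConsensusScore",
    "default_registry",
    "classify_prediction",
    "consensus_score",
    "is_deleterious",
]

#: Weight of a probably-deleterious call in the HARM statistic.
HARM_P_WEIGHT: float = 0.4

_LEVELS = ("D", "P", "T")
_RULES = ("both", "either", "crit1_only", "crit2_only")


class RegistryError(KeyError):
    """Unknown tool, or a categorical code absent from a tool's map."""


@dataclass(frozen=True)
class ToolCriterion:
    """Classification rule for one predictor.

    ``kind`` is ``"categorical"`` (raw codes looked up in ``categorical_map``,
    whose values are D/P/T or None for explicitly-uninformative codes) or
    ``"numeric_threshold"`` (score compared against ``threshold``;
    ``direction`` ``"ge"`` means score >= threshold is deleterious).
    Numeric tools have no P level.
    """

    tool_id: str
    kind: str
    categorical_map: Optional[Mapping[str, Optional[str]]] = None
    threshold: Optional[float] = None
    direction: str = "ge"

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric_threshold"):
            raise ValueError(f"{self.tool_id}: unknown criterion kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categorical_map:
                raise ValueError(f"{self.tool_id}: categorical tool needs a map")
            bad = {v for v in self.categorical_map.values() if v is not None and v not in _LEVELS}
            if bad:
                raise ValueError(f"{self.tool_id}: map targets {bad} not in {_LEVELS}")
        else:
            if self.threshold is None:
                raise ValueError(f"{self.tool_id}: numeric tool needs a threshold")
            if self.direction not in ("ge", "le"):
                raise ValueError(f"{self.tool_id}: direction must be 'ge' or 'le'")

    def classify(self, raw: object) -> Optional[str]:
        """Map one raw prediction to D/P/T, or None for missing."""
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        if self.kind == "numeric_threshold":
            score = float(raw)
            hit = score >= self.threshold if self.direction == "ge" else score <= self.threshold
            return "D" if hit else "T"
        code = str(raw)
        if code not in self.categorical_map:
            raise RegistryError(
                f"tool {self.tool_id}: raw code {code!r} not in categorical map"
            )
        return self.categorical_map[code]


class ToolRegistry:
    """Ordered collection of :class:`ToolCriterion` keyed by tool id."""

    def __init__(self, criteria: list[ToolCriterion]) -> None:
        ids = [c.tool_id for c in criteria]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tool ids in registry")
        self._criteria = {c.tool_id: c for c in criteria}

    def __len__(self) -> int:
        return len(self._criteria)

    def __contains__(self, tool_id: str) -> bool:
        return tool_id in self._criteria

    def __iter__(self):
        return iter(self._criteria)

    @property
    def tool_ids(self) -> list[str]:
        return list(self._criteria)

    def __getitem__(self, tool_id: str) -> ToolCriterion:
        try:
            return self._criteria[tool_id]
        except KeyError:
            raise RegistryError(f"tool {tool_id!r} not in registry") from None

    @classmethod
    def from_yaml(cls, path) -> "ToolRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        criteria = []
        for tool_id, entry in doc["tools"].items():
            if entry["kind"] == "categorical":
                cmap = {
                    str(k): (None if v == "NA" else str(v))
                    for k, v in entry["map"].items()
                }
                criteria.append(ToolCriterion(tool_id, "categorical", categorical_map=cmap))
            else:
                criteria.append(
                    ToolCriterion(
                        tool_id,
                        "numeric_threshold",
                        threshold=float(entry["threshold"]),
                        direction=entry.get("direction", "ge"),
                    )
                )
        return cls(criteria)


def default_registry() -> ToolRegistry:
    """The shipped 12-tool registry (SIFT ... CADD; CADD numeric, cutoff 15)."""
    ref = resources.files("harmburden.data") / "tool_registry.yaml"
    with resources.as_file(ref) as path:
        return ToolRegistry.from_yaml(path)


def classify_prediction(
    tool_id: str, raw: object, registry: Optional[ToolRegistry] = None
) -> Optional[str]:
    """Classify one raw prediction as D, P, T or None (missing)."""
    registry = registry if registry is not None else default_registry()
    return registry[tool_id].classify(raw)


@dataclass(frozen=True)
class ConsensusScore:
    """Per-variant tallies, HARM value and the two criterion flags."""

    nD: int
    nP: int
    nT: int
    n_missing: int
    harm: float
    crit1: bool  # nD > 0
    crit2: bool  # HARM > 0

    @classmethod
    def from_counts(cls, nD: int, nP: int, nT: int, n_missing: int = 0) -> "ConsensusScore":
        harm = nD + HARM_P_WEIGHT * nP - nT
        return cls(nD, nP, nT, n_missing, harm, nD > 0, harm > 0)


def consensus_score(
    levels: Mapping[str, Optional[str]], registry: Optional[ToolRegistry] = None
) -> ConsensusScore:
    """Tally D/P/T levels over the registered tools and compute HARM.

    ``levels`` maps tool id to the classified level (D/P/T or None).  Tools
    absent from the mapping count as missing, so nD + nP + nT + n_missing
    always equals the registry size.
    """
    registry = registry if registry is not None else default_registry()
    unknown = set(levels) - set(registry.tool_ids)
    if unknown:
        raise RegistryError(f"levels for unregistered tools: {sorted(unknown)}")
    nD = nP = nT = 0
    for tool_id in registry.tool_ids:
        level = levels.get(tool_id)
        if level == "D":
            nD += 1
        elif level == "P":
            nP += 1
        elif level == "T":
            nT += 1
        elif level is not None:
            raise ValueError(f"tool {tool_id}: invalid level {level!r}")
    n_missing = len(registry) - nD - nP - nT
    return ConsensusScore.from_counts(nD, nP, nT, n_missing)


def score_variant(
    tool_calls: Mapping[str, object], registry: Optional[ToolRegistry] = None
) -> ConsensusScore:
    """Classify raw tool calls and tally them in one step."""
    registry = registry if registry is not None else default_registry()
    levels = {t: registry[t].classify(raw) for t, raw in tool_calls.items()}
    return consensus_score(levels, registry)


def is_deleterious(score: ConsensusScore, rule: str = "both") -> bool:
    """Apply the configured combination of the two criteria.

    ``both`` (default) requires nD > 0 and HARM > 0; ``either`` accepts one;
    ``crit1_only`` / ``crit2_only`` use a single criterion.
    """
    if rule not in _RULES:
        raise ValueError(f"rule must be one of {_RULES}, got {rule!r}")
    if rule == "both":
        return score.crit1 and score.crit2
    if rule == "either":
        return score.crit1 or score.crit2
    if rule == "crit1_only":
        return score.crit1
    return score.crit2
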
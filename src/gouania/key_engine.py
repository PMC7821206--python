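"""Dichotomous identification-key engine.

A key is a rooted binary tree of couplets. Each couplet offers two contrasting
leads (a/b), each a conjunction of character predicates plus a branch target
(another couplet or a species leaf). Real specimens are routinely incomplete
or contradictory, so evaluation is vote-based per couplet: every character
present in the profile and mentioned by the couplet votes for the lead whose
predicate it satisfies; a unanimous non-empty vote picks that branch, anything
else (conflicting votes, no usable character, or a numeric value falling in
the gap between the two leads' intervals) is ambiguous and both branches are
explored, yielding a candidate set rather than a forced single answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

__all__ = [
    "CharacterProfile",
    "Predicate",
    "Lead",
    "Couplet",
    "KeyDefinition",
    "IdentificationResult",
    "KeyDefinitionError",
    "evaluate_couplet",
    "identify",
    "load_key",
]

#: Allowed states for the categorical key characters (None = missing).
PROFILE_STATES = {
    "dorsal_head_profile": ("straight", "concave"),
    "jaw_angle_extent": (
        "to_anterior_nostril",
        "between_posterior_nostril_and_anterior_eye",
        "to_anterior_eye_or_beyond",
    ),
    "neuromast_groove": ("deep", "shallow"),
    "opercular_edge": (
        "pointed_upper_rounded_lower",
        "two_equal_tips",
        "two_tips_upper_longer_or_equal",
    ),
}

NUMERIC_FIELDS = (
    "caudal_fin_length_pct_sl",
    "pectoral_fin_length_pct_sl",
    "vertebrae_count",
)


class KeyDefinitionError(ValueError):
    """Malformed key: cycle, dangling reference, or invalid leaf structure."""


@dataclass
class CharacterProfile:
    """Key-character states of one specimen; None marks a missing character."""

    dorsal_head_profile: str | None = None
    caudal_fin_length_pct_sl: float | None = None
    pectoral_fin_length_pct_sl: float | None = None
    jaw_angle_extent: str | None = None
    neuromast_groove: str | None = None
    opercular_edge: str | None = None
    vertebrae_count: int | None = None

    def __post_init__(self) -> None:
        for name, states in PROFILE_STATES.items():
            value = getattr(self, name)
            if value is not None and value not in states:
                raise ValueError(f"{name}: unknown state {value!r}; expected {states}")
        for name in ("caudal_fin_length_pct_sl", "pectoral_fin_length_pct_sl"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be positive when present, got {value}")
        if self.vertebrae_count is not None and not 30 <= self.vertebrae_count <= 45:
            raise ValueError(
                f"vertebrae_count out of plausible range [30, 45]: {self.vertebrae_count}"
            )

    def get(self, character: str):
        return getattr(self, character)


@dataclass(frozen=True)
class Predicate:
    """One character test: equality for categorical states, closed interval
    membership for numeric characters."""

    character: str
    op: Literal["eq", "in_interval"]
    value: str | None = None
    lo: float | None = None
    hi: float | None = None

    def matches(self, observed) -> bool:
        if self.op == "eq":
            return observed == self.value
        return self.lo <= observed <= self.hi


@dataclass(frozen=True)
class Lead:
    predicates: tuple[Predicate, ...]
    target: str  # couplet id, or species name when is_leaf
    is_leaf: bool
    note: str | None = None  # geography etc.; metadata, never evidence


@dataclass(frozen=True)
class Couplet:
    id: str
    a: Lead
    b: Lead


@dataclass
class KeyDefinition:
    """Validated rooted binary key."""

    root: str
    couplets: dict[str, Couplet]

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        if self.root not in self.couplets:
            raise KeyDefinitionError(f"root couplet {self.root!r} not defined")
        seen: set[str] = set()
        stack = [self.root]
        incoming: dict[str, int] = {}
        while stack:
            cid = stack.pop()
            if cid in seen:
                raise KeyDefinitionError(f"couplet {cid!r} reachable twice (cycle or DAG)")
            seen.add(cid)
            couplet = self.couplets[cid]
            for lead in (couplet.a, couplet.b):
                if not lead.is_leaf:
                    if lead.target not in self.couplets:
                        raise KeyDefinitionError(
                            f"couplet {cid!r} references undefined couplet {lead.target!r}"
                        )
                    incoming[lead.target] = incoming.get(lead.target, 0) + 1
                    stack.append(lead.target)
        unreachable = set(self.couplets) - seen
        if unreachable:
            raise KeyDefinitionError(f"unreachable couplets: {sorted(unreachable)}")

    @property
    def species(self) -> set[str]:
        """All leaf species of the key."""
        return {
            lead.target
            for couplet in self.couplets.values()
            for lead in (couplet.a, couplet.b)
            if lead.is_leaf
        }


@dataclass
class IdentificationResult:
    candidates: set[str]
    path: list[tuple[str, str]]  # (couplet id, "a" | "b" | "both")
    conflicts: list[str] = field(default_factory=list)

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1

    @property
    def species(self) -> str:
        if not self.unique:
            raise ValueError(f"identification not unique: {sorted(self.candidates)}")
        return next(iter(self.candidates))


def evaluate_couplet(
    profile: CharacterProfile, couplet: Couplet
) -> tuple[Literal["a", "b", "ambiguous"], list[str]]:
    """Vote on one couplet.

    Returns the chosen branch plus the list of characters that voted against
    the majority (non-empty only in the conflicting, hence ambiguous, case).
    A character present in the profile votes "a" if it satisfies an a-lead
    predicate, "b" for a b-lead predicate; satisfying neither (e.g. a caudal
    fin of 13.2 %SL between the 11.1-13.0 and 13.5-17.5 leads) is no vote.
    """
    votes: dict[str, str] = {}
    for branch, lead in (("a", couplet.a), ("b", couplet.b)):
        for pred in lead.predicates:
            observed = profile.get(pred.character)
            if observed is None:
                continue
            if pred.matches(observed):
                if votes.get(pred.character, branch) != branch:
                    votes[pred.character] = "conflict"  # matches both leads
                else:
                    votes[pred.character] = branch
    conflictual = [c for c, v in votes.items() if v == "conflict"]
    cast = {v for v in votes.values() if v != "conflict"}
    if conflictual or len(cast) != 1:
        losers = sorted(set(votes))
        return "ambiguous", losers if len(cast) > 1 or conflictual else []
    return next(iter(cast)), []


def identify(profile: CharacterProfile, key: KeyDefinition) -> IdentificationResult:
    """Run a specimen profile through the key.

    Depth-first; at ambiguous couplets both branches are explored and the
    candidate leaves are unioned, so missing data widens the answer instead
    of failing.
    """
    result = IdentificationResult(candidates=set(), path=[])

    def walk(cid: str) -> None:
        couplet = key.couplets[cid]
        decision, conflicts = evaluate_couplet(profile, couplet)
        if conflicts:
            result.conflicts.extend(f"{cid}:{c}" for c in conflicts)
        result.path.append((cid, decision if decision != "ambiguous" else "both"))
        branches = (decision,) if decision != "ambiguous" else ("a", "b")
        for branch in branches:
            lead = couplet.a if branch == "a" else couplet.b
            if lead.is_leaf:
                result.candidates.add(lead.target)
            else:
                walk(lead.target)

    walk(key.root)
    return result


def _parse_lead(raw: dict) -> Lead:
    preds = []
    for p in raw.get("predicates", []):
        op = p["op"]
        if op == "eq":
            preds.append(Predicate(character=p["character"], op="eq", value=p["value"]))
        elif op == "in_interval":
            lo, hi = float(p["lo"]), float(p["hi"])
            if lo > hi:
                raise KeyDefinitionError(f"predicate interval reversed: {p}")
            preds.append(Predicate(character=p["character"], op="in_interval", lo=lo, hi=hi))
        else:
            raise KeyDefinitionError(f"unknown predicate operator {op!r}")
    nxt = raw["next"]
    if "species" in nxt:
        return Lead(tuple(preds), nxt["species"], True, raw.get("note"))
    if "couplet" in nxt:
        return Lead(tuple(preds), str(nxt["couplet"]), False, raw.get("note"))
    raise KeyDefinitionError(f"lead target must name a species or a couplet: {nxt}")


def load_key(path: str | Path) -> KeyDefinition:
    """Load a key definition from its YAML file format."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        couplets = {
            str(c["id"]): Couplet(str(c["id"]), _parse_lead(c["a"]), _parse_lead(c["b"]))
            for c in raw["couplets"]
        }
        return KeyDefinition(root=str(raw["root"]), couplets=couplets)
    except (KeyError, TypeError) as exc:
        raise KeyDefinitionError(f"malformed key file {path}: {exc}") from exc
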
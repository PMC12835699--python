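"""Variable declarations for mixed discrete/continuous datasets.

A :class:`VariableSpec` declares how a column is treated throughout the
pipeline: discrete variables carry an ordered list of levels and enter the
network as multinomial nodes; continuous variables enter as linear-Gaussian
nodes.  The ``role`` tag groups variables the way clinical network studies
report them (demographic, clinical, cognitive, quality of life), and
``ordered`` controls the numeric coding used when a discrete variable enters
a structural equation model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

DISCRETE = "discrete"
CONTINUOUS = "continuous"

_ROLES = ("demographic", "clinical", "cognitive", "qol")


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one analysis variable.

    Parameters
    ----------
    name
        Unique column name.
    kind
        ``"discrete"`` or ``"continuous"``.
    levels
        Ordered tuple of admissible levels; required (>= 2 entries) for
        discrete variables, must be empty for continuous ones.
    role
        One of ``demographic``, ``clinical``, ``cognitive``, ``qol``.
    ordered
        For discrete variables: whether the level order is meaningful
        (age bands, education bands, employment).  Ordered and binary
        variables are integer-coded for SEM; unordered multi-level ones
        are dummy-coded.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = field(default_factory=tuple)
    role: str = "clinical"
    ordered: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (DISCRETE, CONTINUOUS):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        if self.kind == DISCRETE:
            if len(self.levels) < 2:
                raise ValueError(f"discrete variable {self.name!r} needs >= 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels in {self.name!r}")
        elif self.levels:
            raise ValueError(f"continuous variable {self.name!r} must not declare levels")
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def is_discrete(self) -> bool:
        return self.kind == DISCRETE

    @property
    def is_continuous(self) -> bool:
        return self.kind == CONTINUOUS

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def check_unique(specs: Sequence[VariableSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("variable names must be unique")


def specs_to_json(specs: Iterable[VariableSpec]) -> str:
    payload = [
        {
            "name": s.name,
            "kind": s.kind,
            "levels": list(s.levels),
            "role": s.role,
            "ordered": s.ordered,
        }
        for s in specs
    ]
    return json.dumps(payload, indent=2)


def specs_from_json(text: str) -> list[VariableSpec]:
    payload = json.loads(text)
    return [
        VariableSpec(
            name=entry["name"],
            kind=entry["kind"],
            levels=tuple(entry.get("levels", ())),
            role=entry.get("role", "clinical"),
            ordered=bool(entry.get("ordered", False)),
        )
        for entry in payload
    ]


def save_specs(specs: Iterable[VariableSpec], path: str | Path) -> None:
    Path(path).write_text(specs_to_json(specs))


def load_specs(path: str | Path) -> list[VariableSpec]:
    return specs_from_json(Path(path).read_text())


def catie_roster() -> list[VariableSpec]:
    """The 21-variable roster emulating the CATIE baseline analysis set.

    Six discrete demographics followed by fifteen continuous clinical,
    cognitive and quality-of-life scale scores, in the conventional
    reporting order (demographics, depression/attitude/insight scales,
    MATRICS cognitive domains, PANSS subscales, clinician-rated global
    impressions, quality of life).
    """
    d = []
    d.append(VariableSpec("age_category", DISCRETE, ("<30", "31-45", ">45"),
                          role="demographic", ordered=True))
    d.append(VariableSpec("sex", DISCRETE, ("male", "female"), role="demographic"))
    d.append(VariableSpec("race", DISCRETE,
                          ("white", "black", "asian", "multiple"), role="demographic"))
    d.append(VariableSpec("marital_status", DISCRETE,
                          ("never_married", "ever_married"), role="demographic"))
    d.append(VariableSpec("education", DISCRETE,
                          ("below_hs", "hs_grad", "beyond_hs"),
                          role="demographic", ordered=True))
    d.append(VariableSpec("employment", DISCRETE, ("working", "not_working"),
                          role="demographic", ordered=True))
    for name in ("cdss_total", "dai_total", "itaq_total"):
        d.append(VariableSpec(name, CONTINUOUS, role="clinical"))
    for name in ("matrics_verbal", "matrics_vigilance", "matrics_processing_speed",
                 "matrics_reasoning", "matrics_working_memory"):
        d.append(VariableSpec(name, CONTINUOUS, role="cognitive"))
    for name in ("panss_general", "panss_negative", "panss_positive",
                 "cgi_drug", "cgi_alcohol", "cgi_severity"):
        d.append(VariableSpec(name, CONTINUOUS, role="clinical"))
    d.append(VariableSpec("qol_total", CONTINUOUS, role="qol"))
    return d
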
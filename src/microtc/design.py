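"""Experiment designs: samples, replicate sample sets, factor profiles.

A design assigns every chip to a *sample set* — a named group of replicate
chips sharing one combination of factor levels — and declares, per factor,
which level is the control.  Treatment-over-control (T/C) pairs are then
either enumerated from the factor profiles (see :mod:`microtc.tc`) or
declared explicitly for contrasts the single-differing-factor rule does
not generate (e.g. "32 hr infection vs 9 hr infection").

The on-disk format is a YAML document with keys ``factors``,
``sample_sets`` and optional ``tcs`` (see :func:`read_design`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml

from .errors import DesignError, UnreplicatedError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Sample:
    """One chip: a hybridized array, i.e. one column of the matrix."""

    sample_id: str
    chip_column: str
    description: str = ""


@dataclass(frozen=True)
class FactorDecl:
    """A declared experimental factor with an ordered level list and one control level."""

    name: str
    levels: tuple[str, ...]
    control_level: str

    def __post_init__(self):
        if len(set(self.levels)) != len(self.levels):
            raise DesignError(f"factor {self.name!r}: duplicate levels")
        if self.control_level not in self.levels:
            raise DesignError(
                f"factor {self.name!r}: control level {self.control_level!r} not among levels {list(self.levels)}"
            )

    def level_index(self, level: str) -> int:
        return self.levels.index(level)


@dataclass
class SampleSet:
    """A named group of replicate chips sharing a factor-level profile."""

    name: str
    members: list[Sample]
    profile: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.members) < 2:
            raise UnreplicatedError(
                f"sample set {self.name!r} is unreplicated ({len(self.members)} member); "
                "at least 2 replicate chips are required"
            )
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise DesignError(f"sample set {self.name!r}: duplicate sample IDs")

    @property
    def chip_columns(self) -> list[str]:
        return [m.chip_column for m in self.members]


@dataclass(frozen=True)
class DeclaredTC:
    """An explicitly declared treatment/control contrast."""

    name: str
    treatment: str
    control: str
    description: str = ""


@dataclass
class Design:
    """A parsed, validated experiment design."""

    factors: dict[str, FactorDecl]
    sample_sets: list[SampleSet]
    tcs: list[DeclaredTC] = field(default_factory=list)
    experiment_id: str = ""
    title: str = ""
    description: str = ""

    def sample_set(self, name: str) -> SampleSet:
        for s in self.sample_sets:
            if s.name == name:
                return s
        raise DesignError(f"unknown sample set {name!r}")


@dataclass
class Experiment:
    """One experiment: its matrix, design metadata, sample sets and T/Cs."""

    experiment_id: str
    title: str
    description: str
    matrix: object  # ExpressionMatrix
    sample_sets: list[SampleSet]
    tcs: list = field(default_factory=list)


def _validate_design(design: Design, chip_ids=None) -> None:
    names = [s.name for s in design.sample_sets]
    if len(set(names)) != len(names):
        raise DesignError("duplicate sample set names")
    seen_chips: dict[str, str] = {}
    for sset in design.sample_sets:
        for factor, level in sset.profile.items():
            if factor not in design.factors:
                raise DesignError(
                    f"sample set {sset.name!r} references undeclared factor {factor!r}"
                )
            if level not in design.factors[factor].levels:
                raise DesignError(
                    f"sample set {sset.name!r}: level {level!r} not declared for factor {factor!r}"
                )
        for member in sset.members:
            if member.chip_column in seen_chips:
                raise DesignError(
                    f"chip {member.chip_column!r} assigned to both "
                    f"{seen_chips[member.chip_column]!r} and {sset.name!r}"
                )
            seen_chips[member.chip_column] = sset.name
            if chip_ids is not None and member.chip_column not in chip_ids:
                raise DesignError(
                    f"sample set {sset.name!r}: member chip {member.chip_column!r} not in matrix"
                )
    for tc in design.tcs:
        for ref in (tc.treatment, tc.control):
            if ref not in names:
                raise DesignError(f"T/C {tc.name!r} names unknown sample set {ref!r}")
    if chip_ids is not None:
        unassigned = [c for c in chip_ids if c not in seen_chips]
        if unassigned:
            log.warning("%d chip(s) in matrix but in no sample set: %s", len(unassigned), unassigned)


def _parse_members(raw) -> list[Sample]:
    members = []
    for m in raw:
        if isinstance(m, str):
            members.append(Sample(sample_id=m, chip_column=m))
        elif isinstance(m, dict):
            sid = m.get("sample_id")
            if sid is None:
                raise DesignError(f"sample member missing sample_id: {m!r}")
            members.append(
                Sample(
                    sample_id=str(sid),
                    chip_column=str(m.get("chip_column", sid)),
                    description=str(m.get("description", "")),
                )
            )
        else:
            raise DesignError(f"unparseable sample member: {m!r}")
    return members


def read_design(path, chip_ids=None) -> Design:
    """Parse and validate a YAML design document.

    Expected keys::

        experiment_id / title / description   (optional metadata)
        factors:      {name: {levels: [...], control_level: ...}}
        sample_sets:  {name: {members: [...], profile: {factor: level}}}
        tcs:          {name: {treatment: ..., control: ..., description: ...}}

    ``chip_ids``, when given, is the matrix's chip-column universe; every
    member chip must resolve into it.  Sample sets with fewer than two
    members raise :class:`UnreplicatedError` — unreplicated experiments
    are discarded, never silently admitted.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise DesignError(f"design file {path} is not a mapping")
    return design_from_dict(doc, chip_ids=chip_ids)


def design_from_dict(doc: dict, chip_ids=None) -> Design:
    factors: dict[str, FactorDecl] = {}
    for name, spec in (doc.get("factors") or {}).items():
        if not isinstance(spec, dict) or "levels" not in spec or "control_level" not in spec:
            raise DesignError(f"factor {name!r} needs 'levels' and 'control_level'")
        factors[str(name)] = FactorDecl(
            name=str(name),
            levels=tuple(str(v) for v in spec["levels"]),
            control_level=str(spec["control_level"]),
        )
    raw_sets = doc.get("sample_sets") or {}
    if not raw_sets:
        raise DesignError("design declares no sample sets")
    sample_sets = []
    for name, spec in raw_sets.items():
        members = _parse_members(spec.get("members") or [])
        if len(members) < 2:
            raise UnreplicatedError(
                f"sample set {name!r} is unreplicated ({len(members)} member); "
                "at least 2 replicate chips are required"
            )
        profile = {str(k): str(v) for k, v in (spec.get("profile") or {}).items()}
        sample_sets.append(SampleSet(name=str(name), members=members, profile=profile))
    tcs = []
    for name, spec in (doc.get("tcs") or {}).items():
        tcs.append(
            DeclaredTC(
                name=str(name),
                treatment=str(spec["treatment"]),
                control=str(spec["control"]),
                description=str(spec.get("description", "")),
            )
        )
    design = Design(
        factors=factors,
        sample_sets=sample_sets,
        tcs=tcs,
        experiment_id=str(doc.get("experiment_id", "")),
        title=str(doc.get("title", "")),
        description=str(doc.get("description", "")),
    )
    _validate_design(design, chip_ids=chip_ids)
    return design


def design_to_dict(design: Design) -> dict:
    doc: dict = {}
    if design.experiment_id:
        doc["experiment_id"] = design.experiment_id
    if design.title:
        doc["title"] = design.title
    if design.description:
        doc["description"] = design.description
    doc["factors"] = {
        f.name: {"levels": list(f.levels), "control_level": f.control_level}
        for f in design.factors.values()
    }
    doc["sample_sets"] = {
        s.name: {
            "members": [
                {"sample_id": m.sample_id, "chip_column": m.chip_column, "description": m.description}
                for m in s.members
            ],
            "profile": dict(s.profile),
        }
        for s in design.sample_sets
    }
    if design.tcs:
        doc["tcs"] = {
            t.name: {"treatment": t.treatment, "control": t.control, "description": t.description}
            for t in design.tcs
        }
    return doc


def write_design(design: Design, path) -> None:
    """Serialize a design back to YAML; round-trips with :func:`read_design`."""
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False, allow_unicode=True)
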
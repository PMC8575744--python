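"""Role-based atom selection for bilayer/xanthophyll systems.

Analyses never address raw atom names: they ask for chemical *roles*
(phosphate oxygens ``Op``, carbonyl oxygens ``Oc``, xanthophyll hydroxyl
oxygens, polyene methyls, ...).  An :class:`AtomClassMap` binds each role to
a set of (residue-name pattern, atom-name pattern) rules; a shipped default
covers POPC (Sundaralingam numbering), LUT/ZEA and 3-site water, plus the
pseudo-atom names emitted by :mod:`xanmem.synthetic`.

Custom maps are plain YAML::

    Op:
      - {residues: [POPC], names: [O13, O14]}
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import Atom, Trajectory

__all__ = ["AtomClassMap", "ClassMapError", "ROLES", "default_classmap", "load_classmap"]


class ClassMapError(ValueError):
    """A required role is empty or the map is malformed."""


#: All roles known to the analysis stages.
ROLES = (
    "Op", "Oc", "Oe", "Og",
    "choline_N", "choline_CH3",
    "xan_OH_O", "xan_OH_H",
    "xan_OH_O_beta", "xan_OH_H_beta", "xan_OH_O_eps", "xan_OH_H_eps",
    "MET", "met_beta", "met_eps", "met_c13",
    "C13", "C3", "C3prime",
    "ring_beta_atoms", "ring_eps_atoms",
    "water_O", "water_H",
    "P", "glycerol_O", "acyl_C", "polyene_C",
    "xan_heavy",
)

# Roles that must not overlap (distinct chemistry).
_DISJOINT = [("Op", "Oe"), ("Op", "Oc"), ("Oc", "Og"), ("water_O", "Op")]

# Default rules.  POPC names follow the Sundaralingam head-group numbering;
# LUT/ZEA names follow carotenoid convention with primes on the second
# (epsilon for lutein) ring; the alternative names (OB/HB, MB*, ...) are the
# synthetic-generator pseudo-atom names.
_XAN = ["LUT", "ZEA", "XAN"]
_WATER = ["SOL", "TIP3", "HOH", "WAT"]
_DEFAULT_RULES: dict[str, list[dict]] = {
    "Op": [{"residues": ["POPC"], "names": ["O13", "O14"]}],
    "Oc": [{"residues": ["POPC"], "names": ["O22", "O32"]}],
    "Oe": [{"residues": ["POPC"], "names": ["O11", "O12"]}],
    "Og": [{"residues": ["POPC"], "names": ["O21", "O31"]}],
    "P": [{"residues": ["POPC"], "names": ["P", "P8"]}],
    "glycerol_O": [{"residues": ["POPC"], "names": ["O21", "O31"]}],
    "choline_N": [{"residues": ["POPC"], "names": ["N", "N4"]}],
    "choline_CH3": [{"residues": ["POPC"], "names": ["C13", "C14", "C15"]}],
    "acyl_C": [{"residues": ["POPC"], "names": ["C2?", "C3?", "CA*", "CB*"]}],
    "xan_OH_O_beta": [{"residues": _XAN, "names": ["O3", "OB"]}],
    "xan_OH_H_beta": [{"residues": _XAN, "names": ["H3O", "HO3", "HB"]}],
    "xan_OH_O_eps": [{"residues": _XAN, "names": ["O3'", "O3P", "OE"]}],
    "xan_OH_H_eps": [{"residues": _XAN, "names": ["H3O'", "HO3'", "HE"]}],
    "met_beta": [{"residues": _XAN, "names": ["C19", "C20", "MB*"]}],
    "met_eps": [{"residues": _XAN, "names": ["C19'", "C20'", "ME*"]}],
    "met_c13": [{"residues": _XAN, "names": ["C20", "MB2"]}],
    "C13": [{"residues": _XAN, "names": ["C13", "K13"]}],
    "C3": [{"residues": _XAN, "names": ["C3", "K3"]}],
    "C3prime": [{"residues": _XAN, "names": ["C3'", "C3P", "K3P"]}],
    "ring_beta_atoms": [{"residues": _XAN, "names": ["C1", "C2", "C3", "C4", "C5", "C6",
                                                     "K1", "K2", "K3", "K4", "K5", "K6"]}],
    "ring_eps_atoms": [{"residues": _XAN,
                        "names": ["C1'", "C2'", "C3'", "C4'", "C5'", "C6'",
                                  "K1P", "K2P", "K3P", "K4P", "K5P", "K6P"]}],
    "polyene_C": [{"residues": _XAN, "names": ["C7", "C8", "C9", "C10", "C11", "C12",
                                               "C13", "C14", "C15",
                                               "C7'", "C8'", "C9'", "C10'", "C11'",
                                               "C12'", "C13'", "C14'", "C15'",
                                               "K7", "K8", "K13", "K7P", "K8P", "KP*"]}],
    "water_O": [{"residues": _WATER, "names": ["OW", "O", "OH2"]}],
    "water_H": [{"residues": _WATER, "names": ["HW?", "H1", "H2"]}],
    "xan_heavy": [{"residues": _XAN, "names": ["C*", "O*", "K*", "MB*", "ME*"]}],
}
# Union roles are built from their parts.
_UNION_ROLES = {
    "xan_OH_O": ("xan_OH_O_beta", "xan_OH_O_eps"),
    "xan_OH_H": ("xan_OH_H_beta", "xan_OH_H_eps"),
    "MET": ("met_beta", "met_eps"),
}


def _match(rules: Sequence[Mapping], atom: Atom) -> bool:
    for rule in rules:
        res_ok = any(fnmatch.fnmatchcase(atom.residue_name, p) for p in rule.get("residues", ["*"]))
        name_ok = any(fnmatch.fnmatchcase(atom.name, p) for p in rule.get("names", ["*"]))
        if res_ok and name_ok:
            return True
    return False


@dataclass
class AtomClassMap:
    """Resolved role -> atom-index selections for one topology."""

    selections: dict[str, np.ndarray]
    topology: list[Atom] = field(repr=False, default_factory=list)

    @classmethod
    def from_rules(cls, topology: Sequence[Atom], rules: Mapping[str, Sequence[Mapping]]
                   ) -> "AtomClassMap":
        sels: dict[str, np.ndarray] = {}
        for role in ROLES:
            if role in _UNION_ROLES:
                continue
            role_rules = rules.get(role, [])
            idx = [a.index for a in topology if role_rules and _match(role_rules, a)]
            sels[role] = np.array(sorted(idx), dtype=int)
        for role, parts in _UNION_ROLES.items():
            sels[role] = np.array(sorted(set().union(*(sels[p].tolist() for p in parts))),
                                  dtype=int)
        cm = cls(selections=sels, topology=list(topology))
        cm._validate()
        return cm

    @classmethod
    def default(cls, topology: Sequence[Atom]) -> "AtomClassMap":
        return cls.from_rules(topology, _DEFAULT_RULES)

    def _validate(self):
        for a, b in _DISJOINT:
            inter = np.intersect1d(self.selections.get(a, []), self.selections.get(b, []))
            if inter.size:
                raise ClassMapError(f"roles {a!r} and {b!r} overlap on atoms {inter[:5]}")

    def select(self, role: str) -> np.ndarray:
        if role not in self.selections:
            raise ClassMapError(f"unknown role {role!r}")
        return self.selections[role]

    def require(self, role: str) -> np.ndarray:
        """Selection for ``role``; raises if empty (stage refuses to run)."""
        sel = self.select(role)
        if sel.size == 0:
            raise ClassMapError(
                f"role {role!r} selects no atoms in this topology; "
                "the requesting stage cannot run"
            )
        return sel

    def per_residue(self, role: str) -> dict[tuple[str, int], np.ndarray]:
        """Split a role selection by (residue_name, residue_id)."""
        out: dict[tuple[str, int], list[int]] = {}
        for i in self.select(role):
            a = self.topology[i]
            out.setdefault((a.residue_name, a.residue_id), []).append(i)
        return {k: np.array(v, dtype=int) for k, v in out.items()}

    def xan_residues(self) -> list[tuple[str, int]]:
        """Xanthophyll residues present, ordered by residue id."""
        seen = {}
        for i in self.select("xan_heavy"):
            a = self.topology[i]
            seen[(a.residue_name, a.residue_id)] = None
        return sorted(seen, key=lambda k: k[1])


def default_classmap(traj: Trajectory) -> AtomClassMap:
    return AtomClassMap.default(traj.topology)


def load_classmap(path, traj: Trajectory) -> AtomClassMap:
    """Load role rules from a YAML file and resolve them on ``traj``."""
    with open(path) as fh:
        rules = yaml.safe_load(fh)
    if not isinstance(rules, dict):
        raise ClassMapError(f"{path}: expected a mapping of role -> rules")
    merged = dict(_DEFAULT_RULES)
    merged.update(rules)
    return AtomClassMap.from_rules(traj.topology, merged)
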
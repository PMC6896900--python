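"""Nucleosome complex topology, core/tail region table, and dimer-deletion variants.

A canonical nucleosome has eight histone chains (two copies each of H3, H4,
H2A, H2B; the second copy carries a prime) and two DNA strands.  The partially
disassembled models are built by deleting exactly one hetero-dimer.  Histone
residues are split into a folded *core* and disordered *tail* regions; every
superposition and flexibility analysis excludes the tails, while the contact
analysis keeps them (the tails are the finding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from nucdyn.errors import (
    ClassificationError,
    IncompleteResidueError,
    MissingChainError,
    TopologyError,
    VariantStateError,
)

logger = logging.getLogger(__name__)

HISTONE_ROLES = ("H3", "H4", "H2A", "H2B", "H3'", "H4'", "H2A'", "H2B'")
DNA_ROLES = ("DNA-I", "DNA-J")

#: Default chain-id -> role map following the 1KX5 convention
#: (chains A-H histones, I-J DNA).  Roles are never inferred from sequence.
DEFAULT_CHAIN_MAP: dict[str, str] = {
    "A": "H3",
    "B": "H4",
    "C": "H2A",
    "D": "H2B",
    "E": "H3'",
    "F": "H4'",
    "G": "H2A'",
    "H": "H2B'",
    "I": "DNA-I",
    "J": "DNA-J",
}

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


def _base_role(role: str) -> str:
    """Strip the prime from a histone role (H2A' -> H2A)."""
    return role.rstrip("'")


@dataclass(frozen=True)
class AtomSite:
    """One atom of the complex with its file-order identity and position (A)."""

    atom_id: int
    atom_name: str
    element: str
    chain_id: str
    residue_index: int
    residue_name: str
    position: np.ndarray

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise TopologyError(
                f"atom {self.atom_id} ({self.atom_name}) has invalid position {pos!r}"
            )
        object.__setattr__(self, "position", pos)


class ModelVariant(Enum):
    """The canonical nucleosome and the four single-dimer-deletion models."""

    CANONICAL = "canonical"
    DEL_H3_H4 = "dH3H4"
    DEL_H2A_H2B = "dH2AH2B"
    DEL_H3p_H4p = "dH3pH4p"
    DEL_H2Ap_H2Bp = "dH2ApH2Bp"

    @property
    def deleted_roles(self) -> tuple[str, ...]:
        return _VARIANT_DELETIONS[self]

    @classmethod
    def from_string(cls, name: str) -> "ModelVariant":
        key = (
            name.strip()
            .replace("Δ", "d")
            .replace("delta", "d")
            .replace("/", "")
            .replace("-", "")
            .replace("_", "")
            .replace("’", "p")
            .replace("'", "p")
            .lower()
        )
        for member in cls:
            if member.value.lower() == key:
                return member
        if key == "canonical":
            return cls.CANONICAL
        raise ValueError(f"unknown model variant {name!r}")


_VARIANT_DELETIONS: dict[ModelVariant, tuple[str, ...]] = {
    ModelVariant.CANONICAL: (),
    ModelVariant.DEL_H3_H4: ("H3", "H4"),
    ModelVariant.DEL_H2A_H2B: ("H2A", "H2B"),
    ModelVariant.DEL_H3p_H4p: ("H3'", "H4'"),
    ModelVariant.DEL_H2Ap_H2Bp: ("H2A'", "H2B'"),
}


@dataclass(frozen=True)
class RegionTable:
    """Core/tail residue ranges per histone type (inclusive bounds).

    ``core`` maps the base role to one (first, last) range; ``tails`` maps it
    to one or more ranges (N-terminal for all, plus C-terminal for H2A).
    """

    core: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_CORE)
    )
    tails: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_TAILS)
    )

    def __post_init__(self) -> None:
        for role, (lo, hi) in self.core.items():
            if lo > hi:
                raise TopologyError(f"empty core range for {role}: {lo}-{hi}")
            for tlo, thi in self.tails.get(role, ()):
                if tlo > thi:
                    raise TopologyError(f"empty tail range for {role}: {tlo}-{thi}")
                if max(lo, tlo) <= min(hi, thi):
                    raise TopologyError(
                        f"core and tail ranges overlap for {role}"
                    )

    def classify(self, role: str, residue_index: int) -> str:
        """Return 'core' or 'tail' for a histone residue; raise if in neither."""
        base = _base_role(role)
        if base not in self.core:
            raise ClassificationError(f"no region ranges for histone role {role!r}")
        lo, hi = self.core[base]
        if lo <= residue_index <= hi:
            return "core"
        for tlo, thi in self.tails.get(base, ()):
            if tlo <= residue_index <= thi:
                return "tail"
        raise ClassificationError(
            f"residue {residue_index} of {role} is in neither core nor tail region"
        )

    def tail_ranges(self, role: str) -> tuple[tuple[int, int], ...]:
        return tuple(self.tails.get(_base_role(role), ()))

    def residue_count(self, role: str) -> int:
        """Total residues (core + tails) implied by the table for one chain."""
        base = _base_role(role)
        lo, hi = self.core[base]
        n = hi - lo + 1
        for tlo, thi in self.tails.get(base, ()):
            n += thi - tlo + 1
        return n

    def to_config(self) -> dict[str, str]:
        """Flatten to the plain-text key-value schema (round-trips bit-exactly)."""
        out: dict[str, str] = {}
        for role, (lo, hi) in self.core.items():
            out[f"region.{role}.core"] = f"{lo}-{hi}"
            ranges = self.tails.get(role, ())
            out[f"region.{role}.tails"] = ",".join(f"{a}-{b}" for a, b in ranges)
        return out

    @classmethod
    def from_config(cls, items: Mapping[str, str]) -> "RegionTable":
        core: dict[str, tuple[int, int]] = {}
        tails: dict[str, tuple[tuple[int, int], ...]] = {}
        for key, value in items.items():
            if not key.startswith("region."):
                continue
            _, role, kind = key.split(".", 2)
            if kind == "core":
                lo, hi = value.split("-", 1) if value.count("-") == 1 else _split_range(value)
                core[role] = (int(lo), int(hi))
            elif kind == "tails":
                parts = [p for p in value.split(",") if p.strip()]
                tails[role] = tuple(
                    tuple(int(x) for x in _split_range(p)) for p in parts
                )
        if not core:
            return cls()
        return cls(core=core, tails=tails)


def _split_range(text: str) -> tuple[str, str]:
    """Split 'a-b' allowing negative bounds like '-73-73'."""
    text = text.strip()
    for i in range(1, len(text)):
        if text[i] == "-" and text[i - 1].isdigit():
            return text[:i], text[i + 1 :]
    raise ValueError(f"cannot parse residue range {text!r}")


# Core/tail residue IDs per histone type (file numbering, 1-based).
_DEFAULT_CORE = {
    "H3": (45, 135),
    "H4": (25, 102),
    "H2A": (18, 98),
    "H2B": (35, 122),
}
_DEFAULT_TAILS = {
    "H3": ((1, 44),),
    "H4": ((1, 24),),
    "H2A": ((1, 17), (99, 128)),
    "H2B": ((1, 34),),
}


MASK_LABELS = (
    "align_all_no_tails",
    "align_histone_core_only",
    "dna_c1p",
    "histone_ca",
    "custom",
)


@dataclass(frozen=True)
class SelectionMask:
    """An ordered atom-index subset realizing one of the analysis selections."""

    indices: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1:
            raise TopologyError("mask indices must be a 1-D integer array")
        if self.label not in MASK_LABELS:
            raise TopologyError(f"unknown mask label {self.label!r}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate(self, n_atoms: int) -> None:
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= n_atoms
        ):
            raise TopologyError("mask indices out of range for topology")


class ComplexTopology:
    """Chains, residues and atom roles of a nucleosome-like complex.

    Atoms are stored in file order as parallel numpy arrays; ``chains`` is an
    ordered list of ``(chain_id, role)``.  Chains whose id is not in the chain
    map carry the role ``"other"`` (solvent, ions) and are excluded from every
    analysis mask while remaining in the topology.
    """

    def __init__(
        self,
        chains: Sequence[tuple[str, str]],
        atoms: Iterable[AtomSite],
    ) -> None:
        atoms = list(atoms)
        self.chains: list[tuple[str, str]] = list(chains)
        self._role_of = dict(self.chains)
        if len(self._role_of) != len(self.chains):
            raise TopologyError("duplicate chain ids in topology")
        self.atom_id = np.array([a.atom_id for a in atoms], dtype=np.int64)
        self.atom_name = np.array([a.atom_name for a in atoms], dtype=object)
        self.element = np.array([a.element.upper() for a in atoms], dtype=object)
        self.chain_id = np.array([a.chain_id for a in atoms], dtype=object)
        self.residue_index = np.array([a.residue_index for a in atoms], dtype=np.int64)
        self.residue_name = np.array([a.residue_name for a in atoms], dtype=object)
        unknown = set(self.chain_id) - set(self._role_of)
        if unknown:
            raise TopologyError(f"atoms reference chains not in topology: {unknown}")

    # -- basic queries -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return int(self.atom_id.size)

    def role_of(self, chain_id: str) -> str:
        return self._role_of[chain_id]

    def chain_ids_for_roles(self, roles: Iterable[str]) -> list[str]:
        wanted = set(roles)
        return [cid for cid, role in self.chains if role in wanted]

    @property
    def histone_chain_ids(self) -> list[str]:
        return [cid for cid, role in self.chains if role in HISTONE_ROLES]

    @property
    def dna_chain_ids(self) -> list[str]:
        return [cid for cid, role in self.chains if role in DNA_ROLES]

    @property
    def is_canonical(self) -> bool:
        roles = {role for _, role in self.chains}
        return set(HISTONE_ROLES) <= roles and set(DNA_ROLES) <= roles

    def heavy_mask(self) -> np.ndarray:
        return ~np.isin(self.element, list(_HYDROGEN_ELEMENTS))

    def chain_atom_indices(self, chain_id: str) -> np.ndarray:
        return np.flatnonzero(self.chain_id == chain_id)

    def atoms(self, positions: np.ndarray | None = None) -> list[AtomSite]:
        """Materialize AtomSite objects (positions default to zeros)."""
        if positions is None:
            positions = np.zeros((self.n_atoms, 3))
        return [
            AtomSite(
                int(self.atom_id[i]),
                str(self.atom_name[i]),
                str(self.element[i]),
                str(self.chain_id[i]),
                int(self.residue_index[i]),
                str(self.residue_name[i]),
                positions[i],
            )
            for i in range(self.n_atoms)
        ]

    def residues(self, chain_id: str) -> np.ndarray:
        """Sorted unique residue indices of one chain."""
        return np.unique(self.residue_index[self.chain_id == chain_id])

    def subset(self, atom_indices: np.ndarray, chains: Sequence[tuple[str, str]]) -> "ComplexTopology":
        sub = ComplexTopology.__new__(ComplexTopology)
        sub.chains = list(chains)
        sub._role_of = dict(sub.chains)
        sub.atom_id = self.atom_id[atom_indices]
        sub.atom_name = self.atom_name[atom_indices]
        sub.element = self.element[atom_indices]
        sub.chain_id = self.chain_id[atom_indices]
        sub.residue_index = self.residue_index[atom_indices]
        sub.residue_name = self.residue_name[atom_indices]
        return sub


def build_variant(
    topology: ComplexTopology, variant: ModelVariant
) -> tuple[ComplexTopology, np.ndarray]:
    """Delete one hetero-dimer from a canonical topology.

    Returns the reduced topology and the atom indices (into the canonical
    topology) of the surviving atoms, so coordinates can be filtered in step.
    DNA and the remaining histone chains are untouched and keep file order.
    """
    roles_present = {role for _, role in topology.chains}
    if variant is ModelVariant.CANONICAL:
        return topology, np.arange(topology.n_atoms)
    if not set(HISTONE_ROLES) <= roles_present:
        raise VariantStateError(
            "dimer deletion requires a canonical topology with all eight histone chains"
        )
    doomed_roles = set(variant.deleted_roles)
    doomed_chains = set(topology.chain_ids_for_roles(doomed_roles))
    if len(doomed_chains) != len(doomed_roles):
        missing = doomed_roles - {topology.role_of(c) for c in doomed_chains}
        raise MissingChainError(f"variant chains absent from topology: {missing}")
    keep = ~np.isin(topology.chain_id, list(doomed_chains))
    keep_idx = np.flatnonzero(keep)
    chains = [(cid, role) for cid, role in topology.chains if cid not in doomed_chains]
    return topology.subset(keep_idx, chains), keep_idx


def make_selection(
    topology: ComplexTopology,
    region_table: RegionTable,
    label: str,
    strict: bool = True,
) -> SelectionMask:
    """Build the atom mask for one of the named analysis selections.

    ``align_all_no_tails``: heavy atoms of all DNA and histone chains, minus
    histone tail residues.  ``align_histone_core_only``: additionally drops
    all DNA.  ``dna_c1p``/``histone_ca``: one representative backbone atom per
    nucleotide / amino acid.  Residues listed in the region table but absent
    from the structure are skipped (crystal structures truncate tails); with
    ``strict`` a residue lacking its representative atom raises.
    """
    if label not in MASK_LABELS or label == "custom":
        raise TopologyError(f"cannot construct a mask for label {label!r}")
    heavy = topology.heavy_mask()
    histone_ids = set(topology.histone_chain_ids)
    dna_ids = set(topology.dna_chain_ids)

    if label in ("align_all_no_tails", "align_histone_core_only"):
        include = np.zeros(topology.n_atoms, dtype=bool)
        if label == "align_all_no_tails":
            include |= np.isin(topology.chain_id, list(dna_ids))
        for cid in histone_ids:
            role = topology.role_of(cid)
            on_chain = topology.chain_id == cid
            for res in topology.residues(cid):
                if region_table.classify(role, int(res)) == "core":
                    include |= on_chain & (topology.residue_index == res)
        return SelectionMask(np.flatnonzero(include & heavy), label)

    if label == "dna_c1p":
        chain_set, atom_name = dna_ids, "C1'"
    else:  # histone_ca
        chain_set, atom_name = histone_ids, "CA"
    picked: list[int] = []
    for cid, _role in topology.chains:
        if cid not in chain_set:
            continue
        on_chain = topology.chain_id == cid
        for res in topology.residues(cid):
            hits = np.flatnonzero(
                on_chain
                & (topology.residue_index == res)
                & (topology.atom_name == atom_name)
            )
            if hits.size == 0:
                if strict:
                    raise IncompleteResidueError(
                        f"residue {res} of chain {cid} lacks atom {atom_name}"
                    )
                logger.warning(
                    "skipping residue %s of chain %s: no %s atom", res, cid, atom_name
                )
                continue
            picked.append(int(hits[0]))
    return SelectionMask(np.asarray(picked, dtype=np.intp), label)


def mask_labels_for_atoms(
    topology: ComplexTopology, mask: SelectionMask
) -> list[tuple[str, int]]:
    """(chain_id, residue_index) labels for each atom of a mask, in mask order."""
    return [
        (str(topology.chain_id[i]), int(topology.residue_index[i]))
        for i in mask.indices
    ]
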
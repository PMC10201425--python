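"""In-memory containers for labeled multi-frame structures.

A :class:`Trajectory` is an ordered stack of frames sharing one
:class:`Topology` (atom names, residue ids/names, elements). Coordinates are
float64 Å. A :class:`Frame` is a lightweight view of one model. The
:class:`AtomMap` names the six active-site roles used by the reaction
coordinates: the general-acid nitrogen C10:N3 and its proton, the substrate
acceptor O6mG:N1, the leaving-group oxygen O6mG:O6, the transferable methyl
carbon Cm and the nucleophile A63:N1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

#: Canonical active-site roles, in reaction-coordinate order.
ROLES: tuple[str, ...] = (
    "C10:N3",
    "H(N3)",
    "O6mG:N1",
    "O6mG:O6",
    "Cm",
    "A63:N1",
)


class MissingAtomError(KeyError):
    """A mapped role has no matching atom in the topology."""


@dataclass(eq=False)
class Topology:
    """Per-atom labels shared by all frames of a trajectory."""

    atom_names: tuple[str, ...]
    residue_ids: np.ndarray  # int, 1-based, shape (n_atoms,)
    residue_names: tuple[str, ...]
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        n = len(self.atom_names)
        if not (len(self.residue_names) == n == self.residue_ids.shape[0] == len(self.elements)):
            raise ValueError("topology arrays must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def find(self, residue_id: int, atom_name: str) -> int:
        """Index of the atom with the given 1-based residue id and name."""
        hits = np.flatnonzero(
            (self.residue_ids == residue_id)
            & (np.asarray(self.atom_names) == atom_name)
        )
        if hits.size == 0:
            raise MissingAtomError(f"no atom {atom_name!r} in residue {residue_id}")
        return int(hits[0])

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask selecting non-hydrogen atoms."""
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)


@dataclass(eq=False)
class Frame:
    """One model: a topology plus (n_atoms, 3) coordinates in Å."""

    topology: Topology
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )

    def position(self, residue_id: int, atom_name: str) -> np.ndarray:
        return self.coords[self.topology.find(residue_id, atom_name)]


@dataclass(eq=False)
class Trajectory:
    """A stack of frames over one topology.

    ``bfactors`` optionally carries per-atom crystallographic B-values (Å²)
    from the reference model the trajectory was read with.
    """

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    bfactors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(f"bad trajectory coords shape {self.coords.shape}")
        if self.bfactors is not None:
            self.bfactors = np.asarray(self.bfactors, dtype=float)
            if self.bfactors.shape != (self.topology.n_atoms,):
                raise ValueError("bfactors must be per-atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(self.topology, self.coords[i])

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass
class AtomMap:
    """Maps the six active-site roles to (residue_id, atom_name) addresses."""

    mapping: Mapping[str, tuple[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.mapping]
        if missing:
            raise ValueError(f"atom map is missing roles: {missing}")

    def resolve(self, topology: Topology) -> dict[str, int]:
        """Role → atom index; raises MissingAtomError naming the role."""
        out: dict[str, int] = {}
        for role in ROLES:
            resid, name = self.mapping[role]
            try:
                out[role] = topology.find(resid, name)
            except MissingAtomError as exc:
                raise MissingAtomError(
                    f"role {role!r} → residue {resid} atom {name!r} not found"
                ) from exc
        return out

    @classmethod
    def default_synthetic(cls) -> "AtomMap":
        """Map matching structures built by the synthetic trajectory generator."""
        return cls(
            {
                "C10:N3": (10, "N3"),
                "H(N3)": (10, "H3"),
                "O6mG:N1": (91, "N1"),
                "O6mG:O6": (91, "O6"),
                "Cm": (91, "CM"),
                "A63:N1": (63, "N1"),
            }
        )

    @classmethod
    def from_dict(cls, data: Mapping[str, Sequence]) -> "AtomMap":
        return cls({k: (int(v[0]), str(v[1])) for k, v in data.items()})

    def to_dict(self) -> dict[str, list]:
        return {k: [int(v[0]), str(v[1])] for k, v in self.mapping.items()}
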
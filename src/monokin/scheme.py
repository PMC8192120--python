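"""Markov-state representation of an ion-coupled transporter cycle.

A :class:`KineticScheme` is an undirected graph of conformational states
connected by reversible transitions. Each transition carries a base forward
and reverse rate, an equivalent charge ``zQ`` (elementary charges moved
inward during the forward step), and optional ligand couplings: a direction
whose rate is multiplied by the concentration of a named species on one side
of the membrane (pseudo-first-order mass action).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

SPECIES = ("Na", "K", "Cl", "H", "Li", "S")
SIDES = ("in", "out")
CONFORMATIONS = ("outward", "occluded", "inward", "conducting")


@dataclass
class State:
    """A conformational state of the transporter.

    ``bound_ligands`` maps species name to the number of bound copies; absent
    species are unbound.
    """

    name: str
    conformation: str = "outward"
    bound_ligands: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.conformation not in CONFORMATIONS:
            raise ValueError(
                f"unknown conformation {self.conformation!r} for state {self.name!r}"
            )
        for species, count in self.bound_ligands.items():
            if count < 0:
                raise ValueError(f"negative ligand count for {species} in {self.name}")

    def ligand_count(self, species: str) -> int:
        return self.bound_ligands.get(species, 0)


@dataclass
class Transition:
    """A reversible edge between two states.

    Rates are in s⁻¹ for unimolecular directions and M⁻¹·s⁻¹ for
    ligand-coupled (bimolecular) directions. ``zQ`` is the equivalent charge
    moved inward during the forward step; with the symmetric-barrier rate law
    the forward rate gains a factor exp(−zQ·F·V/2RT) and the reverse the
    inverse factor.
    """

    from_state: str
    to_state: str
    k0_fwd: float
    k0_rev: float
    zQ: float = 0.0
    ligand_fwd: tuple[str, str] | None = None  # (species, side)
    ligand_rev: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.k0_fwd < 0 or self.k0_rev < 0:
            raise ValueError(
                f"negative rate on transition {self.from_state}->{self.to_state}"
            )
        if not np.isfinite(self.zQ):
            raise ValueError("zQ must be finite")
        for lig in (self.ligand_fwd, self.ligand_rev):
            if lig is not None:
                species, side = lig
                if side not in SIDES:
                    raise ValueError(f"unknown membrane side {side!r}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.from_state, self.to_state))


@dataclass
class KineticScheme:
    """A connected reaction graph of states and reversible transitions."""

    states: list[State]
    transitions: list[Transition]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {s.name: i for i, s in enumerate(self.states)}
        if len(self._index) != len(self.states):
            raise ValueError("state names must be unique")
        for tr in self.transitions:
            for name in (tr.from_state, tr.to_state):
                if name not in self._index:
                    raise ValueError(f"transition references unknown state {name!r}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def state_index(self, name: str) -> int:
        return self._index[name]

    def state(self, name: str) -> State:
        return self.states[self._index[name]]

    def find_transition(self, a: str, b: str) -> Transition:
        """The unique transition joining states ``a`` and ``b`` (any order)."""
        pair = frozenset((a, b))
        for tr in self.transitions:
            if tr.pair == pair:
                return tr
        raise KeyError(f"no transition between {a!r} and {b!r}")

    def is_connected(self) -> bool:
        if not self.states:
            return False
        adj: dict[str, set[str]] = {s.name: set() for s in self.states}
        for tr in self.transitions:
            adj[tr.from_state].add(tr.to_state)
            adj[tr.to_state].add(tr.from_state)
        seen = {self.states[0].name}
        stack = [self.states[0].name]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == len(self.states)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "states": [
                {
                    "name": s.name,
                    "conformation": s.conformation,
                    "bound_ligands": dict(s.bound_ligands),
                }
                for s in self.states
            ],
            "transitions": [
                {
                    "from": tr.from_state,
                    "to": tr.to_state,
                    "k0_fwd": float(tr.k0_fwd),
                    "k0_rev": float(tr.k0_rev),
                    "zQ": float(tr.zQ),
                    "ligand_fwd": list(tr.ligand_fwd) if tr.ligand_fwd else None,
                    "ligand_rev": list(tr.ligand_rev) if tr.ligand_rev else None,
                }
                for tr in self.transitions
            ],
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "KineticScheme":
        states = [
            State(
                name=s["name"],
                conformation=s.get("conformation", "outward"),
                bound_ligands={k: int(v) for k, v in (s.get("bound_ligands") or {}).items()},
            )
            for s in payload["states"]
        ]
        transitions = [
            Transition(
                from_state=t["from"],
                to_state=t["to"],
                k0_fwd=float(t["k0_fwd"]),
                k0_rev=float(t["k0_rev"]),
                zQ=float(t.get("zQ", 0.0)),
                ligand_fwd=tuple(t["ligand_fwd"]) if t.get("ligand_fwd") else None,
                ligand_rev=tuple(t["ligand_rev"]) if t.get("ligand_rev") else None,
            )
            for t in payload["transitions"]
        ]
        return cls(states=states, transitions=transitions, metadata=payload.get("metadata", {}))


@dataclass
class IonConditions:
    """Per-species concentrations (M) on each side of the membrane.

    ``concentrations`` maps ``(species, side)`` to molarity; anything not
    listed is zero. Inert replacement cations (NMDG⁺) are represented simply
    by the absence of coupled species.
    """

    concentrations: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.concentrations.items():
            if value < 0:
                raise ValueError(f"negative concentration for {key}")

    def get(self, species: str, side: str) -> float:
        return self.concentrations.get((species, side), 0.0)

    def with_updates(self, updates: dict[tuple[str, str], float]) -> "IonConditions":
        merged = dict(self.concentrations)
        merged.update(updates)
        return IonConditions(merged)

    @classmethod
    def build(
        cls,
        *,
        Na_out: float = 0.0,
        Na_in: float = 0.0,
        K_out: float = 0.0,
        K_in: float = 0.0,
        Cl_out: float = 0.0,
        Cl_in: float = 0.0,
        Li_out: float = 0.0,
        Li_in: float = 0.0,
        S_out: float = 0.0,
        S_in: float = 0.0,
        pH_out: float = 7.4,
        pH_in: float = 7.2,
    ) -> "IonConditions":
        conc = {
            ("Na", "out"): Na_out,
            ("Na", "in"): Na_in,
            ("K", "out"): K_out,
            ("K", "in"): K_in,
            ("Cl", "out"): Cl_out,
            ("Cl", "in"): Cl_in,
            ("Li", "out"): Li_out,
            ("Li", "in"): Li_in,
            ("S", "out"): S_out,
            ("S", "in"): S_in,
            ("H", "out"): 10.0 ** (-pH_out),
            ("H", "in"): 10.0 ** (-pH_in),
        }
        return cls(conc)

    def to_dict(self) -> dict:
        return {f"{species}_{side}": float(v) for (species, side), v in self.concentrations.items()}

    @classmethod
    def from_dict(cls, payload: dict) -> "IonConditions":
        conc = {}
        for key, value in payload.items():
            species, side = key.rsplit("_", 1)
            conc[(species, side)] = float(value)
        return cls(conc)


def validate_scheme(scheme: KineticScheme) -> list[str]:
    """Structural diagnostics for a scheme; an empty list means valid.

    Checks connectivity, duplicate edges, and consistency between each
    transition's declared ligand couplings and the ligand counts of its end
    states (a direction must be ligand-coupled iff the destination gains a
    copy of that species).
    """
    diagnostics: list[str] = []
    if not scheme.is_connected():
        diagnostics.append("scheme graph is not connected")

    seen_pairs: set[frozenset[str]] = set()
    for tr in scheme.transitions:
        if tr.pair in seen_pairs:
            diagnostics.append(
                f"duplicate transition between {tr.from_state} and {tr.to_state}"
            )
        seen_pairs.add(tr.pair)

    for tr in scheme.transitions:
        src = scheme.state(tr.from_state)
        dst = scheme.state(tr.to_state)
        species_involved = set(src.bound_ligands) | set(dst.bound_ligands)
        for lig in (tr.ligand_fwd, tr.ligand_rev):
            if lig is not None:
                species_involved.add(lig[0])
        for species in species_involved:
            delta = dst.ligand_count(species) - src.ligand_count(species)
            fwd_binds = tr.ligand_fwd is not None and tr.ligand_fwd[0] == species
            rev_binds = tr.ligand_rev is not None and tr.ligand_rev[0] == species
            if delta > 0 and not fwd_binds:
                diagnostics.append(
                    f"{tr.from_state}->{tr.to_state} gains {species} without a "
                    "forward ligand coupling"
                )
            if delta < 0 and not rev_binds:
                diagnostics.append(
                    f"{tr.to_state}->{tr.from_state} gains {species} without a "
                    "reverse ligand coupling"
                )
            if delta == 0 and (fwd_binds or rev_binds):
                diagnostics.append(
                    f"{tr.from_state}<->{tr.to_state} declares a {species} coupling "
                    "but ligand counts do not change"
                )
    return diagnostics


def independent_cycles(scheme: KineticScheme) -> list[list[str]]:
    """A cycle basis of the scheme graph, each cycle as an ordered closed walk.

    Built from a spanning tree: every non-tree edge closes exactly one
    fundamental cycle. Used to enforce thermodynamic consistency.
    """
    parent: dict[str, str | None] = {}
    order: list[str] = []
    adj: dict[str, list[tuple[str, Transition]]] = {s.name: [] for s in scheme.states}
    for tr in scheme.transitions:
        adj[tr.from_state].append((tr.to_state, tr))
        adj[tr.to_state].append((tr.from_state, tr))

    root = scheme.states[0].name
    parent[root] = None
    stack = [root]
    tree_edges: set[frozenset[str]] = set()
    while stack:
        node = stack.pop()
        order.append(node)
        for nxt, tr in adj[node]:
            if nxt not in parent:
                parent[nxt] = node
                tree_edges.add(tr.pair)
                stack.append(nxt)

    def path_to_root(node: str) -> list[str]:
        path = [node]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])  # type: ignore[arg-type]
        return path

    cycles: list[list[str]] = []
    for tr in scheme.transitions:
        if tr.pair in tree_edges:
            continue
        pa = path_to_root(tr.from_state)
        pb = path_to_root(tr.to_state)
        common = None
        set_pa = set(pa)
        for node in pb:
            if node in set_pa:
                common = node
                break
        assert common is not None
        walk = pa[: pa.index(common) + 1]
        walk += list(reversed(pb[: pb.index(common)]))
        walk.append(tr.from_state)  # close the loop through the non-tree edge
        cycles.append(walk)
    return cycles
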
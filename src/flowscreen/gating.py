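"""Hierarchical gating: named populations defined by per-channel bounds.

A :class:`GatingStrategy` is a tree of gates. Each node selects events from its
parent population by a per-channel predicate, so a named population contains
exactly the events satisfying the conjunction of its own gate and every
ancestor gate.

Boundary semantics, applied consistently across the package: the *positive*
side of any bound is strict (``x > bound``); the negative/low side is the
complement (``x <= bound``). Range gates select ``lo < x <= hi``. Four sibling
quadrant gates on the same channel pair therefore partition their parent
exactly.

Gate kinds
----------
``above``     events with ``x > bound`` on one channel (threshold-above)
``below``     events with ``x <= bound`` (threshold-below; e.g. CD38low)
``range``     events with ``lo < x <= hi``
``quadrant``  one quadrant of a 2D plane: ``quadrant`` is two signs, e.g.
              ``"+-"`` meaning first channel positive, second channel not
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .events import EventTable

__all__ = ["Gate", "GatingStrategy", "apply_gating"]

ROOT = "root"
_KINDS = ("above", "below", "range", "quadrant")


@dataclass(frozen=True)
class Gate:
    """One node of a gating tree."""

    name: str
    channels: tuple[str, ...]
    kind: str
    bounds: tuple[float, ...]
    parent: str = ROOT
    quadrant: str | None = None  # two of "+"/"-", quadrant gates only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"gate {self.name!r}: unknown kind {self.kind!r}")
        n_ch, n_b = len(self.channels), len(self.bounds)
        expect = {"above": (1, 1), "below": (1, 1), "range": (1, 2), "quadrant": (2, 2)}[self.kind]
        if (n_ch, n_b) != expect:
            raise ConfigurationError(
                f"gate {self.name!r}: kind {self.kind!r} needs {expect[0]} channel(s) "
                f"and {expect[1]} bound(s), got {n_ch}/{n_b}"
            )
        if not all(np.isfinite(self.bounds)):
            raise ConfigurationError(f"gate {self.name!r}: non-finite bounds {self.bounds}")
        if self.kind == "range" and self.bounds[0] > self.bounds[1]:
            raise ConfigurationError(f"gate {self.name!r}: range lo > hi")
        if self.kind == "quadrant":
            if self.quadrant is None or len(self.quadrant) != 2 or not set(self.quadrant) <= {"+", "-"}:
                raise ConfigurationError(
                    f"gate {self.name!r}: quadrant selector must be two of '+'/'-', got {self.quadrant!r}"
                )

    def mask(self, table: EventTable) -> np.ndarray:
        """Boolean event mask for this gate alone (ancestors not applied)."""
        for ch in self.channels:
            if ch not in table.channels:
                raise ConfigurationError(
                    f"gate {self.name!r} references missing channel {ch!r}"
                )
        if self.kind == "above":
            return table.values(self.channels[0]) > self.bounds[0]
        if self.kind == "below":
            return table.values(self.channels[0]) <= self.bounds[0]
        if self.kind == "range":
            x = table.values(self.channels[0])
            return (x > self.bounds[0]) & (x <= self.bounds[1])
        masks = []
        for ch, b, sign in zip(self.channels, self.bounds, self.quadrant):  # type: ignore[arg-type]
            x = table.values(ch)
            masks.append(x > b if sign == "+" else x <= b)
        return masks[0] & masks[1]


class GatingStrategy:
    """An acyclic tree of uniquely named gates rooted at ``"root"``."""

    def __init__(self, gates: Iterable[Gate]):
        self.gates: dict[str, Gate] = {}
        for g in gates:
            if g.name == ROOT:
                raise ConfigurationError('"root" is reserved for the ungated population')
            if g.name in self.gates:
                raise ConfigurationError(f"duplicate gate name {g.name!r}")
            self.gates[g.name] = g
        for g in self.gates.values():
            if g.parent != ROOT and g.parent not in self.gates:
                raise ConfigurationError(f"gate {g.name!r}: unknown parent {g.parent!r}")
        # Cycle check by walking to root from every node.
        for g in self.gates.values():
            seen, cur = {g.name}, g.parent
            while cur != ROOT:
                if cur in seen:
                    raise ConfigurationError(f"gating tree has a cycle through {cur!r}")
                seen.add(cur)
                cur = self.gates[cur].parent

    def ancestry(self, name: str) -> list[Gate]:
        """Gates from the root down to (and including) ``name``."""
        chain: list[Gate] = []
        cur = name
        while cur != ROOT:
            gate = self.gates[cur]
            chain.append(gate)
            cur = gate.parent
        return chain[::-1]

    @classmethod
    def from_dict(cls, spec: Mapping | Sequence[Mapping]) -> "GatingStrategy":
        """Build from parsed YAML/JSON: a list of node mappings.

        Keys per node: ``name``, ``channel`` or ``channels``, ``kind``,
        ``bound`` or ``bounds``, optional ``parent`` (default root) and
        ``quadrant``.
        """
        nodes = spec.get("gates", spec) if isinstance(spec, Mapping) else spec
        gates = []
        for node in nodes:
            channels = node.get("channels", node.get("channel"))
            if isinstance(channels, str):
                channels = [channels]
            bounds = node.get("bounds", node.get("bound"))
            if isinstance(bounds, (int, float)):
                bounds = [bounds]
            gates.append(
                Gate(
                    name=str(node["name"]),
                    channels=tuple(str(c) for c in channels),
                    kind=str(node["kind"]),
                    bounds=tuple(float(b) for b in bounds),
                    parent=str(node.get("parent", ROOT)),
                    quadrant=node.get("quadrant"),
                )
            )
        return cls(gates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GatingStrategy":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def apply_gating(events: EventTable, strategy: GatingStrategy) -> dict[str, EventTable]:
    """Apply a gating tree; return population name -> gated event table.

    The result includes ``"root"`` (the input) plus every named node. Each
    population is the conjunction of its own gate with all ancestor gates;
    gating is idempotent and children are row-subsets of their parents.
    """
    masks: dict[str, np.ndarray] = {ROOT: np.ones(events.n_events, dtype=bool)}

    def _mask(name: str) -> np.ndarray:
        if name not in masks:
            gate = strategy.gates[name]
            masks[name] = _mask(gate.parent) & gate.mask(events)
        return masks[name]

    out = {ROOT: events}
    for name in strategy.gates:
        out[name] = events.select(_mask(name))
    return out
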
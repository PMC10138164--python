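"""Snapshot-based dynamic networks and temporal edge-list I/O.

A dynamic network is an ordered sequence of T undirected simple graphs
(snapshots) over a common node universe.  Its elementary unit is the
*event*: a temporal edge (u, v, t) meaning the interaction u--v is active
at integer time point t.  The on-disk dialect is a plain-text TSV with one
event per line (``u<TAB>v<TAB>t``), ``#``-prefixed comments, an optional
``#T=<n>`` header preserving empty trailing/embedded snapshots, and
optional ``#node <id>`` headers declaring event-less nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Event",
    "TemporalNetwork",
    "read_temporal_edgelist",
    "write_temporal_edgelist",
    "snapshot_at",
]


@dataclass(frozen=True)
class Event:
    """A temporal edge: interaction (u, v) active at time point t."""

    u: str
    v: str
    t: int

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError(f"self-loop event on node {self.u!r}")
        if self.t < 0:
            raise ValueError(f"negative time point {self.t}")

    def canonical(self) -> tuple[str, str, int]:
        """(min(u,v), max(u,v), t) — undirected events compare equal."""
        u, v = (self.u, self.v) if self.u <= self.v else (self.v, self.u)
        return (u, v, self.t)


def _canon(u: str, v: str, t: int) -> tuple[str, str, int]:
    return (u, v, t) if u <= v else (v, u, t)


@dataclass
class TemporalNetwork:
    """An ordered sequence of snapshots sharing one node universe.

    Parameters
    ----------
    name
        Free-form label (e.g. "G" for the source, "H" for the target).
    nodes
        The node universe.  Nodes may be silent (degree 0) in any snapshot.
    events
        Set of canonical (u, v, t) triples, u < v, 0 <= t < n_timepoints.
    n_timepoints
        Number of snapshots T.  Defaults to max(t)+1 over the events.
    """

    name: str
    nodes: frozenset[str]
    events: frozenset[tuple[str, str, int]]
    n_timepoints: int = -1

    def __post_init__(self) -> None:
        self.events = frozenset(_canon(*e) for e in self.events)
        self.nodes = frozenset(self.nodes) | {
            n for u, v, _ in self.events for n in (u, v)
        }
        if self.n_timepoints < 0:
            self.n_timepoints = max((t for _, _, t in self.events), default=0) + 1
        if self.n_timepoints < 1:
            raise ValueError("a temporal network needs at least one time point")
        for u, v, t in self.events:
            if u == v:
                raise ValueError(f"self-loop event on node {u!r}")
            if not 0 <= t < self.n_timepoints:
                raise ValueError(
                    f"event ({u}, {v}, {t}) outside time range [0, {self.n_timepoints})"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def edges_at(self, t: int) -> set[tuple[str, str]]:
        """Undirected edge set of snapshot t (canonical (u, v), u < v)."""
        if not 0 <= t < self.n_timepoints:
            raise IndexError(
                f"time point {t} out of range [0, {self.n_timepoints})"
            )
        return {(u, v) for u, v, s in self.events if s == t}

    def snapshot(self, t: int) -> nx.Graph:
        """Undirected simple graph of snapshot t over the full node universe.

        Silent nodes are kept as isolated vertices so that downstream
        components (walk sampling, vocabulary building) see every node at
        every time point.
        """
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(self.edges_at(t))
        return g

    @property
    def snapshots(self) -> list[nx.Graph]:
        return [self.snapshot(t) for t in range(self.n_timepoints)]

    # -- transforms --------------------------------------------------------

    def relabel(self, mapping: Mapping[str, str], name: str | None = None) -> "TemporalNetwork":
        """Return a copy with node ids renamed through an injective map."""
        m = dict(mapping)
        if len(set(m.values())) != len(m):
            raise ValueError("relabel mapping must be injective")
        return TemporalNetwork(
            name=name if name is not None else self.name,
            nodes=frozenset(m.get(n, n) for n in self.nodes),
            events=frozenset(
                _canon(m.get(u, u), m.get(v, v), t) for u, v, t in self.events
            ),
            n_timepoints=self.n_timepoints,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TemporalNetwork({self.name!r}, n_nodes={self.n_nodes}, "
            f"n_events={self.n_events}, T={self.n_timepoints})"
        )


def read_temporal_edgelist(path, name: str | None = None) -> TemporalNetwork:
    """Parse a temporal edge list TSV into a :class:`TemporalNetwork`.

    Each non-comment line carries at least three whitespace-separated
    fields ``u v t`` with ``t`` a non-negative integer.  Duplicate events
    collapse; ``(u,v,t)`` and ``(v,u,t)`` are the same event.  Raises
    ``ValueError`` naming the offending line on malformed input, and on an
    empty file ("no events").
    """
    events: set[tuple[str, str, int]] = set()
    declared: set[str] = set()
    header_T: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("T="):
                    try:
                        header_T = int(body[2:])
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{lineno}: malformed #T= header: {line!r}"
                        ) from exc
                elif body.startswith("node "):
                    declared.add(body[5:].strip())
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'u v t', got {line!r}"
                )
            u, v, t_str = fields[0], fields[1], fields[2]
            try:
                t = int(t_str)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer time point {t_str!r}"
                ) from exc
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative time point {t}")
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on node {u!r}")
            events.add(_canon(u, v, t))
    if not events and not declared:
        raise ValueError(f"{path}: no events")
    T = max((t for _, _, t in events), default=0) + 1
    if header_T is not None:
        if header_T < T:
            raise ValueError(
                f"{path}: #T={header_T} smaller than max time index + 1 = {T}"
            )
        T = header_T
    return TemporalNetwork(
        name=name if name is not None else str(path),
        nodes=frozenset(declared),
        events=frozenset(events),
        n_timepoints=T,
    )


def write_temporal_edgelist(network: TemporalNetwork, path) -> None:
    """Write one ``u<TAB>v<TAB>t`` line per event, sorted by (t, u, v).

    A ``#T=<n>`` header records the snapshot count so empty snapshots
    survive a round trip; event-less nodes are declared via ``#node``
    headers.  ``read_temporal_edgelist ∘ write_temporal_edgelist`` is the
    identity on (nodes, events, T).
    """
    touched = {n for u, v, _ in network.events for n in (u, v)}
    with open(path, "w") as fh:
        fh.write(f"#T={network.n_timepoints}\n")
        for node in sorted(network.nodes - touched):
            fh.write(f"#node {node}\n")
        for u, v, t in sorted(network.events, key=lambda e: (e[2], e[0], e[1])):
            fh.write(f"{u}\t{v}\t{t}\n")


def snapshot_at(network: TemporalNetwork, t: int) -> nx.Graph:
    """The undirected simple graph of snapshot ``t`` (0-based)."""
    return network.snapshot(t)
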
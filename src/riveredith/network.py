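"""Single-outlet dendritic river networks.

A river network is represented as a rooted tree of *reaches* (segments not
interrupted by confluences), each draining into at most one downstream
neighbour.  Reaches — not junction nodes — are the habitat unit: every
derived quantity (drainage area, Strahler order, hydraulics, communities)
lives on reaches.

Units are SI with two conventions from river science: lengths in metres,
contributing/drainage areas in km², open-water source areas in m².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

from .errors import ConnectivityError, ReachLookupError, TopologyError

__all__ = [
    "Reach",
    "RiverNetwork",
    "SamplingSite",
    "build_network",
    "accumulate_drainage_area",
    "strahler_order",
    "upstream_set",
    "path_metrics",
    "flow_connected",
    "partition_reaches",
]

#: Conventions for which parts of the endpoint reaches count toward the
#: along-stream path length L_ij (and travel time) from a source reach i to
#: a sampling reach j:
#:
#: - ``"half"``      molecules originate and are sampled mid-reach: half of
#:                   i, half of j, everything in between (unbiased default).
#: - ``"full"``      origin at the upstream end of i, sampling at the
#:                   upstream end of j: all of i, none of j.
#: - ``"exclusive"`` origin at the downstream end of i: only the reaches
#:                   strictly between i and j.
#:
#: All conventions give L = 0 when i = j.
PATH_ENDPOINT_CONVENTIONS = ("half", "full", "exclusive")
DEFAULT_PATH_ENDPOINTS = "half"


@dataclass
class Reach:
    """One river segment and its (partly derived) attributes.

    Hydraulic fields are ``None`` until :func:`riveredith.hydrology.
    extrapolate_hydraulics` loads a season.
    """

    id: str
    downstream_id: Optional[str]
    length: float                      # m
    local_area: float                  # km², local contributing area
    drainage_area: Optional[float] = None   # km², derived
    strahler: Optional[int] = None
    width: Optional[float] = None      # m
    depth: Optional[float] = None      # m
    discharge: Optional[float] = None  # m³/s, seasonal
    velocity: Optional[float] = None   # m/s, seasonal

    @property
    def source_area(self) -> Optional[float]:
        """Open-water surface of the reach in m² (length × width)."""
        if self.width is None:
            return None
        return self.length * self.width


@dataclass
class SamplingSite:
    """An eDNA sampling location, pinned to a reach."""

    site_id: str
    reach_id: str
    seasons_sampled: tuple[str, ...]

    def sampled_in(self, season: str) -> bool:
        return season in self.seasons_sampled


class RiverNetwork:
    """A validated single-outlet tree of reaches.

    Construct through :func:`build_network`; the constructor assumes the
    topology has already been checked.
    """

    def __init__(self, reaches: dict[str, Reach], outlet_id: str,
                 season_tag: Optional[str] = None):
        self.reaches = reaches
        self.outlet_id = outlet_id
        self.season_tag = season_tag
        # reaches draining directly into each reach
        self._upstream: dict[str, list[str]] = {rid: [] for rid in reaches}
        for r in reaches.values():
            if r.downstream_id is not None:
                self._upstream[r.downstream_id].append(r.id)
        self._topo_order = self._compute_topo_order()

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.reaches)

    def __contains__(self, reach_id: str) -> bool:
        return reach_id in self.reaches

    def __iter__(self) -> Iterator[Reach]:
        return iter(self.reaches.values())

    def __getitem__(self, reach_id: str) -> Reach:
        try:
            return self.reaches[reach_id]
        except KeyError:
            raise ReachLookupError(reach_id) from None

    @property
    def reach_ids(self) -> list[str]:
        """Reach ids in upstream-to-downstream (topological) order."""
        return list(self._topo_order)

    def upstream_neighbors(self, reach_id: str) -> list[str]:
        if reach_id not in self.reaches:
            raise ReachLookupError(reach_id)
        return list(self._upstream[reach_id])

    def _compute_topo_order(self) -> list[str]:
        # Kahn ordering on the drainage DAG: every reach appears after all
        # reaches upstream of it.
        order: list[str] = []
        indeg = {rid: len(ups) for rid, ups in self._upstream.items()}
        frontier = sorted(rid for rid, k in indeg.items() if k == 0)
        while frontier:
            rid = frontier.pop()
            order.append(rid)
            down = self.reaches[rid].downstream_id
            if down is not None:
                indeg[down] -= 1
                if indeg[down] == 0:
                    frontier.append(down)
        return order

    def copy(self) -> "RiverNetwork":
        return RiverNetwork({rid: replace(r) for rid, r in self.reaches.items()},
                            self.outlet_id, self.season_tag)

    def total_length(self) -> float:
        return sum(r.length for r in self.reaches.values())


def build_network(edge_records: Iterable[tuple]) -> RiverNetwork:
    """Assemble and validate a network from ``(id, downstream_id, length,
    local_area)`` records.

    ``downstream_id`` is ``None`` (or empty) for the outlet.  The function
    rejects cycles, multiple outlets, disconnected reaches, duplicate ids
    and non-positive lengths.  Derived attributes (drainage area, Strahler
    order, hydraulics) are left unset.
    """
    records = list(edge_records)
    if not records:
        raise ValueError("empty edge-record list")

    reaches: dict[str, Reach] = {}
    for rid, down, length, local_area in records:
        rid = str(rid)
        down = None if down in (None, "") else str(down)
        if rid in reaches:
            raise ValueError(f"duplicate reach id {rid!r}")
        if not length > 0:
            raise ValueError(f"reach {rid!r}: length must be > 0, got {length}")
        if local_area < 0:
            raise ValueError(f"reach {rid!r}: negative local area {local_area}")
        reaches[rid] = Reach(id=rid, downstream_id=down, length=float(length),
                             local_area=float(local_area))

    outlets = [r.id for r in reaches.values() if r.downstream_id is None]
    if len(outlets) != 1:
        raise TopologyError(f"expected exactly one outlet, found {len(outlets)}: "
                            f"{sorted(outlets)}")
    for r in reaches.values():
        if r.downstream_id is not None and r.downstream_id not in reaches:
            raise TopologyError(f"reach {r.id!r} drains to unknown reach "
                                f"{r.downstream_id!r}")

    g = nx.DiGraph()
    g.add_nodes_from(reaches)
    g.add_edges_from((r.id, r.downstream_id) for r in reaches.values()
                     if r.downstream_id is not None)
    if not nx.is_directed_acyclic_graph(g):
        raise TopologyError("cycle detected in downstream relation")
    if not nx.is_weakly_connected(g):
        raise TopologyError("network is not connected to a single outlet")

    return RiverNetwork(reaches, outlets[0])


def accumulate_drainage_area(net: RiverNetwork) -> RiverNetwork:
    """Fill each reach's drainage area: the sum of local contributing areas
    over its upstream set, itself included.  Mutates and returns ``net``."""
    for rid in net.reach_ids:  # upstream first
        r = net[rid]
        r.drainage_area = r.local_area + sum(
            net[u].drainage_area for u in net.upstream_neighbors(rid))
    return net


def strahler_order(net: RiverNetwork) -> dict[str, int]:
    """Strahler stream order per reach.

    Headwaters are order 1; a confluence where the maximum upstream order k
    arrives from two or more branches yields k+1, otherwise the maximum is
    kept.  Results are also stored on the reaches.
    """
    orders: dict[str, int] = {}
    for rid in net.reach_ids:
        ups = net.upstream_neighbors(rid)
        if not ups:
            orders[rid] = 1
        else:
            up_orders = [orders[u] for u in ups]
            k = max(up_orders)
            orders[rid] = k + 1 if up_orders.count(k) >= 2 else k
        net[rid].strahler = orders[rid]
    return orders


def upstream_set(net: RiverNetwork, j: str) -> set[str]:
    """γ(j): the ids of all reaches upstream of ``j``, ``j`` included."""
    if j not in net:
        raise ReachLookupError(j)
    result = {j}
    stack = list(net.upstream_neighbors(j))
    while stack:
        rid = stack.pop()
        result.add(rid)
        stack.extend(net.upstream_neighbors(rid))
    return result


def _downstream_path(net: RiverNetwork, i: str, j: str) -> list[str]:
    """Reach ids on the flow path from i to j, inclusive of both."""
    path = [i]
    rid = i
    while rid != j:
        down = net[rid].downstream_id
        if down is None:
            raise ConnectivityError(f"{i!r} is not upstream of {j!r}")
        path.append(down)
        rid = down
    return path


def path_metrics(net: RiverNetwork, i: str, j: str,
                 endpoints: str = DEFAULT_PATH_ENDPOINTS) -> tuple[float, float]:
    """Along-stream distance L_ij (m) and travel time (s) from reach i to
    reach j, i upstream of j.

    The travel time sums length/velocity reach by reach, so dividing L_ij by
    it recovers the harmonic-mean velocity of the transit.  ``endpoints``
    selects how much of the two endpoint reaches counts
    (see :data:`PATH_ENDPOINT_CONVENTIONS`); i = j always gives (0, 0).
    """
    if i not in net:
        raise ReachLookupError(i)
    if j not in net:
        raise ReachLookupError(j)
    if endpoints not in PATH_ENDPOINT_CONVENTIONS:
        raise ValueError(f"unknown endpoint convention {endpoints!r}")
    if i == j:
        return 0.0, 0.0
    path = _downstream_path(net, i, j)
    w_first = {"half": 0.5, "full": 1.0, "exclusive": 0.0}[endpoints]
    w_last = {"half": 0.5, "full": 0.0, "exclusive": 0.0}[endpoints]
    weights = [w_first] + [1.0] * (len(path) - 2) + [w_last]
    L = 0.0
    t = 0.0
    for rid, w in zip(path, weights):
        if w == 0.0:
            continue
        r = net[rid]
        L += w * r.length
        if r.velocity is None or r.velocity <= 0:
            raise ValueError(f"reach {rid!r} has no positive velocity loaded")
        t += w * r.length / r.velocity
    return L, t


def flow_connected(net: RiverNetwork, i: str, j: str) -> bool:
    """True when one of the two reaches lies on the downstream path of the
    other (a reach is flow-connected to itself)."""
    if i not in net:
        raise ReachLookupError(i)
    if j not in net:
        raise ReachLookupError(j)
    for a, b in ((i, j), (j, i)):
        rid: Optional[str] = a
        while rid is not None:
            if rid == b:
                return True
            rid = net[rid].downstream_id
    return False


def partition_reaches(net: RiverNetwork, max_length: float) -> RiverNetwork:
    """Split every reach longer than ``max_length`` into equal sub-reaches.

    A reach of length L > max_length becomes ceil(L / max_length) sub-reaches
    in series, each of length L/n, with the local contributing area divided
    equally among them.  Total length and total local area are conserved;
    topology is otherwise unchanged.  Sub-reach ids are ``"<id>.1"`` (most
    upstream) through ``"<id>.<n>"``; the returned network carries a
    ``parent_map`` attribute from new ids to original ids.  Derived
    attributes are not carried over.
    """
    if not max_length > 0:
        raise ValueError("max_length must be positive")

    records: list[tuple] = []
    parent_map: dict[str, str] = {}
    # where upstream neighbours of an original reach should now drain
    head_of: dict[str, str] = {}
    tail_of: dict[str, str] = {}
    split_count: dict[str, int] = {}
    for r in net:
        n = math.ceil(r.length / max_length) if r.length > max_length else 1
        split_count[r.id] = n
        if n == 1:
            head_of[r.id] = tail_of[r.id] = r.id
        else:
            head_of[r.id] = f"{r.id}.1"
            tail_of[r.id] = f"{r.id}.{n}"

    for r in net:
        n = split_count[r.id]
        down_head = None if r.downstream_id is None else head_of[r.downstream_id]
        if n == 1:
            records.append((r.id, down_head, r.length, r.local_area))
            parent_map[r.id] = r.id
        else:
            sub_len = r.length / n
            sub_area = r.local_area / n
            for k in range(1, n + 1):
                sid = f"{r.id}.{k}"
                down = f"{r.id}.{k + 1}" if k < n else down_head
                records.append((sid, down, sub_len, sub_area))
                parent_map[sid] = r.id

    new = build_network(records)
    new.parent_map = parent_map  # type: ignore[attr-defined]
    return new
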
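"""Data model and file I/O for multi-layer directed binary networks.

A :class:`MultiplexNetwork` holds M binary directed layers over one shared
roster of people. The roster distinguishes *egos* (deciders whose outgoing
ties were recorded) from roster-only *alters* (valid targets who made no
recorded decisions themselves). Cells of the tie tensor ``G[j, k, m]`` are
0, 1, or unobserved; the diagonal and every non-ego-sender row are
structurally unobserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UNOBSERVED",
    "Roster",
    "LayerSpec",
    "MultiplexNetwork",
    "DyadIndex",
    "read_multiplex",
    "write_multiplex",
    "to_dyad_table",
]

#: Sentinel stored in ``G`` for structurally missing cells.
UNOBSERVED: int = -1

_TRUE_STRINGS = {"1", "true", "t", "yes"}
_FALSE_STRINGS = {"0", "false", "f", "no"}


class MultiplexError(ValueError):
    """Raised on invalid network data or malformed input files."""


@dataclass(frozen=True)
class Roster:
    """Ordered person roster with an ego indicator per person.

    Parameters
    ----------
    ids
        Unique person identifiers (opaque strings), in roster order.
    is_ego
        Boolean per person; True marks a decider whose outgoing ties were
        observed.
    """

    ids: tuple[str, ...]
    is_ego: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        is_ego = np.asarray(self.is_ego, dtype=bool)
        object.__setattr__(self, "is_ego", is_ego)
        if len(ids) == 0:
            raise MultiplexError("roster must contain at least one person")
        if len(set(ids)) != len(ids):
            raise MultiplexError("roster ids must be unique")
        if is_ego.shape != (len(ids),):
            raise MultiplexError("is_ego must align with ids")
        if not is_ego.any():
            raise MultiplexError("roster must contain at least one ego")

    @property
    def size(self) -> int:
        return len(self.ids)

    @property
    def n_egos(self) -> int:
        return int(self.is_ego.sum())

    @property
    def ego_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_ego)

    def index_of(self, person: str) -> int:
        try:
            return self._index[person]
        except AttributeError:
            object.__setattr__(
                self, "_index", {p: i for i, p in enumerate(self.ids)}
            )
            return self._index[person]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Roster):
            return NotImplemented
        return self.ids == other.ids and bool(
            np.array_equal(self.is_ego, other.is_ego)
        )


@dataclass(frozen=True)
class LayerSpec:
    """A named network layer; ``role`` is descriptive metadata only."""

    name: str
    role: str = "behavior"

    def __post_init__(self) -> None:
        if self.role not in ("behavior", "rating"):
            raise MultiplexError(
                f"layer role must be 'behavior' or 'rating', got {self.role!r}"
            )


@dataclass
class MultiplexNetwork:
    """Roster plus M binary directed layers with an observability mask.

    ``G`` has shape ``(J, J, M)`` with entries in ``{0, 1, UNOBSERVED}``,
    indexed ``(sender, receiver, layer)``. Diagonal cells and cells whose
    sender is not an ego are always unobserved.
    """

    roster: Roster
    layers: list[LayerSpec]
    G: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        J = self.roster.size
        self.layers = list(self.layers)
        if len(self.layers) < 1:
            raise MultiplexError("at least one layer is required")
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise MultiplexError("layer names must be unique")
        G = np.asarray(self.G, dtype=np.int8)
        if G.shape != (J, J, self.n_layers):
            raise MultiplexError(
                f"G must have shape {(J, J, self.n_layers)}, got {G.shape}"
            )
        if not np.isin(G, (0, 1, UNOBSERVED)).all():
            raise MultiplexError("G entries must be 0, 1, or UNOBSERVED")
        diag = np.arange(J)
        if (G[diag, diag, :] != UNOBSERVED).any():
            raise MultiplexError("diagonal cells must be unobserved")
        non_ego = ~self.roster.is_ego
        if (G[non_ego, :, :] != UNOBSERVED).any():
            raise MultiplexError("non-ego senders must be unobserved")
        expected = self.roster.is_ego[:, None] & ~np.eye(J, dtype=bool)
        if (G[expected, :] == UNOBSERVED).any():
            raise MultiplexError("ego-sender off-diagonal cells must be observed")
        self.G = G

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean ``(J, J)`` mask of observed (ego-sender, non-self) cells."""
        J = self.roster.size
        return self.roster.is_ego[:, None] & ~np.eye(J, dtype=bool)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum()) * self.n_layers

    def layer_index(self, name: str) -> int:
        for i, l in enumerate(self.layers):
            if l.name == name:
                return i
        raise MultiplexError(f"unknown layer {name!r}")

    def layer_adjacency(self, layer: int | str) -> np.ndarray:
        """Binary adjacency of one layer; unobserved cells count as absent."""
        m = layer if isinstance(layer, int) else self.layer_index(layer)
        return (self.G[:, :, m] == 1).astype(np.int8)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiplexNetwork):
            return NotImplemented
        return (
            self.roster == other.roster
            and self.layers == other.layers
            and bool(np.array_equal(self.G, other.G))
        )


class DyadIndex:
    """Bijection between ordered non-self pairs and (dyad, direction) slots.

    Unordered pairs ``{j, k}`` with ``j < k`` are enumerated in
    lexicographic order; direction 0 is the low-to-high slot ``j -> k``,
    direction 1 the reverse. Dyad count is ``J(J-1)/2``.
    """

    def __init__(self, J: int):
        if J < 2:
            raise MultiplexError("need at least two people to form dyads")
        self.J = J
        lo, hi = np.triu_indices(J, k=1)
        self.lo = lo
        self.hi = hi
        self._lookup = np.full((J, J), -1, dtype=np.int64)
        self._lookup[lo, hi] = np.arange(lo.size)
        self._lookup[hi, lo] = np.arange(lo.size)

    @property
    def n_dyads(self) -> int:
        return self.lo.size

    def dyad_of(self, j: int, k: int) -> tuple[int, int]:
        """Return (dyad index, direction) for the ordered pair ``j -> k``."""
        if j == k:
            raise MultiplexError("self-pairs have no dyad slot")
        return int(self._lookup[j, k]), int(j > k)

    def endpoints(self, dyad: int, direction: int) -> tuple[int, int]:
        """Sender/receiver person indices of a (dyad, direction) slot."""
        j, k = int(self.lo[dyad]), int(self.hi[dyad])
        return (j, k) if direction == 0 else (k, j)


def _parse_bool(value: object) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise MultiplexError(f"cannot interpret {value!r} as a boolean ego flag")


def read_roster(roster_path) -> Roster:
    """Read a roster CSV with columns ``id,is_ego``."""
    df = pd.read_csv(roster_path, dtype=str)
    missing = {"id", "is_ego"} - set(df.columns)
    if missing:
        raise MultiplexError(f"roster file lacks columns {sorted(missing)}")
    ids = [str(v) for v in df["id"]]
    is_ego = np.array([_parse_bool(v) for v in df["is_ego"]], dtype=bool)
    return Roster(ids=tuple(ids), is_ego=is_ego)


def read_multiplex(
    edge_list_path,
    roster_path,
    layers: list[str] | list[LayerSpec] | None = None,
) -> MultiplexNetwork:
    """Read an edge-list CSV plus roster CSV into a validated network.

    The edge list has header ``layer,sender,receiver,value``; the value
    column is optional and defaults to 1 (one row per placed tie). Absent
    (ego-sender, receiver, layer) triples are observed zeros, because a
    roster-based instrument records only the ties that were placed.
    Non-ego senders may not appear: their outgoing cells are unobserved.

    Parameters
    ----------
    layers
        Optional explicit layer list (names or :class:`LayerSpec`). When
        omitted, layers are inferred from the edge list in order of first
        appearance; a network whose edge list is empty then has no
        inferable layers and raises.
    """
    roster = read_roster(roster_path)
    df = pd.read_csv(edge_list_path, dtype=str)
    required = {"layer", "sender", "receiver"}
    missing = required - set(df.columns)
    if missing:
        raise MultiplexError(f"edge list lacks columns {sorted(missing)}")
    if "value" in df.columns:
        values = df["value"].fillna("1")
    else:
        values = pd.Series(["1"] * len(df))
    parsed = []
    for v in values:
        if str(v).strip() not in ("0", "1"):
            raise MultiplexError(f"edge value must be 0 or 1, got {v!r}")
        parsed.append(int(str(v).strip()))

    if layers is None:
        seen: list[str] = []
        for name in df["layer"]:
            if name not in seen:
                seen.append(str(name))
        if not seen:
            raise MultiplexError(
                "cannot infer layers from an empty edge list; pass layers="
            )
        specs = [LayerSpec(n) for n in seen]
    else:
        specs = [l if isinstance(l, LayerSpec) else LayerSpec(str(l)) for l in layers]
    layer_idx = {l.name: i for i, l in enumerate(specs)}

    J, M = roster.size, len(specs)
    G = np.full((J, J, M), UNOBSERVED, dtype=np.int8)
    obs = roster.is_ego[:, None] & ~np.eye(J, dtype=bool)
    G[obs, :] = 0

    seen_triples: dict[tuple[int, int, int], int] = {}
    for (layer, sender, receiver), value in zip(
        zip(df["layer"], df["sender"], df["receiver"]), parsed
    ):
        if str(layer) not in layer_idx:
            raise MultiplexError(f"edge references unknown layer {layer!r}")
        m = layer_idx[str(layer)]
        try:
            j = roster.index_of(str(sender))
            k = roster.index_of(str(receiver))
        except KeyError as exc:
            raise MultiplexError(f"unknown person id {exc.args[0]!r} in edge list")
        if j == k:
            raise MultiplexError(f"self-tie listed for {sender!r}; self-pairs are excluded")
        if not roster.is_ego[j]:
            raise MultiplexError(
                f"edge from non-ego sender {sender!r}; only ego decisions are observed"
            )
        key = (j, k, m)
        if key in seen_triples and seen_triples[key] != value:
            raise MultiplexError(
                f"contradictory duplicate entries for ({sender}, {receiver}, {layer})"
            )
        seen_triples[key] = value
        G[j, k, m] = value
    return MultiplexNetwork(roster=roster, layers=specs, G=G)


def write_multiplex(net: MultiplexNetwork, edge_list_path, roster_path) -> None:
    """Write a network as edge-list + roster CSVs.

    Only cells observed as 1 produce edge rows; observed zeros are implied
    by the roster. Reading the files back with the network's layer list
    reproduces ``G`` exactly.
    """
    rows = []
    ids = net.roster.ids
    for m, spec in enumerate(net.layers):
        senders, receivers = np.nonzero(net.G[:, :, m] == 1)
        for j, k in zip(senders, receivers):
            rows.append((spec.name, ids[j], ids[k], 1))
    pd.DataFrame(rows, columns=["layer", "sender", "receiver", "value"]).to_csv(
        edge_list_path, index=False
    )
    pd.DataFrame(
        {"id": ids, "is_ego": net.roster.is_ego.astype(int)}
    ).to_csv(roster_path, index=False)


def to_dyad_table(net: MultiplexNetwork) -> pd.DataFrame:
    """Flatten ``G`` into one row per (dyad, direction, layer) slot.

    Returns exactly ``2 * M * J(J-1)/2`` rows with columns
    ``dyad, direction, layer, sender, receiver, value`` where ``value`` is
    nullable (pd.NA for unobserved cells). The mapping is invertible.
    """
    J, M = net.roster.size, net.n_layers
    idx = DyadIndex(J)
    ids = net.roster.ids
    records = []
    for d in range(idx.n_dyads):
        for direction in (0, 1):
            j, k = idx.endpoints(d, direction)
            for m in range(M):
                g = int(net.G[j, k, m])
                records.append(
                    (d, direction, net.layers[m].name, ids[j], ids[k],
                     pd.NA if g == UNOBSERVED else g)
                )
    return pd.DataFrame(
        records,
        columns=["dyad", "direction", "layer", "sender", "receiver", "value"],
    ).astype({"value": "Int64"})


def from_dyad_table(
    table: pd.DataFrame, roster: Roster, layers: list[LayerSpec]
) -> MultiplexNetwork:
    """Inverse of :func:`to_dyad_table`."""
    J, M = roster.size, len(layers)
    layer_idx = {l.name: i for i, l in enumerate(layers)}
    G = np.full((J, J, M), UNOBSERVED, dtype=np.int8)
    for row in table.itertuples(index=False):
        j = roster.index_of(str(row.sender))
        k = roster.index_of(str(row.receiver))
        m = layer_idx[str(row.layer)]
        G[j, k, m] = UNOBSERVED if pd.isna(row.value) else int(row.value)
    return MultiplexNetwork(roster=roster, layers=layers, G=G)
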
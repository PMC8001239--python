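"""Generalized forecast-error variance decompositions and the connectedness
index family built on them.

Shares are ordering-invariant: the decomposition conditions each shock on the
full innovation covariance rather than on a Cholesky ordering, so rows must be
normalized to sum to one.  All indices are reported in percent:

* ``FROM_i``  — share of i's forecast-error variance due to the other series;
* ``TO_i``    — share of the others' variance due to shocks in i;
* ``NTDCI_i`` — TO minus FROM (net transmission);
* ``NPDCI``   — antisymmetric matrix of bilateral net spillovers;
* ``TCI``     — network-wide average of the FROM (equivalently TO) shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tvp_var import TVPVARState, VARParams, ma_coefficients

__all__ = [
    "FEVDMatrix",
    "ConnectednessTable",
    "NodeRole",
    "Edge",
    "gfevd",
    "connectedness_indices",
    "dynamic_connectedness",
    "average_table",
    "classify_nodes",
    "export_network",
    "tci_series",
    "ntdci_frame",
    "write_edge_list",
    "write_dot",
]


@dataclass(frozen=True)
class FEVDMatrix:
    """Row-normalized H-step generalized variance-decomposition matrix.

    Entry (i, j) is the share of series i's forecast-error variance
    attributable to shocks in series j; every row sums to one.
    """

    horizon: int
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FEVD matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix dimension")
        if np.any(v < -1e-12):
            raise ValueError("FEVD shares must be non-negative")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("FEVD rows must sum to 1 within 1e-10")

    @property
    def n_series(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ConnectednessTable:
    """The full index family derived from one FEVD matrix (percent units)."""

    label: object  # period index or "static"
    fevd: FEVDMatrix
    to_others: np.ndarray
    from_others: np.ndarray
    ntdci: np.ndarray
    npdci: np.ndarray
    tci: float
    tci_denominator: str = "N"

    @property
    def labels(self) -> tuple[str, ...]:
        return self.fevd.labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "to_others": self.to_others,
                "from_others": self.from_others,
                "ntdci": self.ntdci,
            },
            index=list(self.labels),
        )


@dataclass(frozen=True)
class NodeRole:
    """Transmitter/receiver classification of one series over a sample."""

    series_id: str
    mean_ntdci: float
    role: str  # "net transmitter" | "net receiver"
    purity: str  # "pure transmitter" | "pure receiver" | "in-between"


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    weight: float


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"CCS{i + 1}" for i in range(n))


def gfevd(params: VARParams, horizon: int, labels: tuple[str, ...] | None = None) -> FEVDMatrix:
    """Generalized H-step forecast-error variance decomposition.

    The raw share of series i's variance due to shock j is

        theta_ij = sigma_jj^-1 * sum_{h<H} (e_i' Psi_h Sigma e_j)^2
                   / sum_{h<H} e_i' Psi_h Sigma Psi_h' e_i

    after which each row is scaled to sum to one.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    sigma = params.sigma
    diag = np.diag(sigma)
    if np.any(diag <= 0):
        raise ValueError("innovation covariance must have a strictly positive diagonal")
    n = params.n_series
    psi = ma_coefficients(params, horizon - 1)  # Psi_0..Psi_{H-1}
    num = np.zeros((n, n))
    den = np.zeros(n)
    for h in range(horizon):
        ps = psi[h] @ sigma
        num += ps**2
        den += np.diag(ps @ psi[h].T)
    theta = num / diag[np.newaxis, :] / den[:, np.newaxis]
    fevd = theta / theta.sum(axis=1, keepdims=True)
    return FEVDMatrix(horizon=horizon, values=fevd, labels=labels or _default_labels(n))


def connectedness_indices(
    fevd: FEVDMatrix,
    label: object = "static",
    tci_denominator: str = "N",
    npdci_per_node: bool = False,
) -> ConnectednessTable:
    """Derive the index family from a normalized FEVD matrix.

    ``tci_denominator`` switches between the N (default) and N-1 scalings of
    the total index; ``npdci_per_node`` divides pairwise indices by N, which
    breaks the exact NTDCI = row-sum identity and is off by default.
    """
    phi = fevd.values
    n = fevd.n_series
    off = phi - np.diag(np.diag(phi))
    from_others = 100.0 * off.sum(axis=1)
    to_others = 100.0 * off.sum(axis=0)
    ntdci = to_others - from_others
    npdci = 100.0 * (phi.T - phi)
    if npdci_per_node:
        npdci = npdci / n
    denom = {"N": n, "N-1": n - 1}.get(tci_denominator)
    if denom is None:
        raise ValueError("tci_denominator must be 'N' or 'N-1'")
    tci = 100.0 * off.sum() / denom
    return ConnectednessTable(
        label=label,
        fevd=fevd,
        to_others=to_others,
        from_others=from_others,
        ntdci=ntdci,
        npdci=npdci,
        tci=tci,
        tci_denominator=tci_denominator,
    )


def dynamic_connectedness(
    states: list[TVPVARState],
    horizon: int,
    labels: tuple[str, ...] | None = None,
    **index_kwargs,
) -> list[ConnectednessTable]:
    """One connectedness table per filter state, order preserved."""
    if not states:
        raise ValueError("state sequence is empty")
    tables = []
    for state in states:
        try:
            fevd = gfevd(state.params(), horizon, labels=labels)
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise type(exc)(f"decomposition failed at period {state.t}: {exc}") from exc
        tables.append(connectedness_indices(fevd, label=state.t, **index_kwargs))
    return tables


def average_table(tables: list[ConnectednessTable], **index_kwargs) -> ConnectednessTable:
    """Static table: element-wise mean of the FEVD matrices, indices recomputed."""
    if not tables:
        raise ValueError("cannot average an empty table sequence")
    mean_fevd = np.mean([t.fevd.values for t in tables], axis=0)
    fevd = FEVDMatrix(horizon=tables[0].fevd.horizon, values=mean_fevd, labels=tables[0].labels)
    kwargs = {"tci_denominator": tables[0].tci_denominator, **index_kwargs}
    return connectedness_indices(fevd, label="static", **kwargs)


def tci_series(tables: list[ConnectednessTable]) -> pd.Series:
    return pd.Series([t.tci for t in tables], index=[t.label for t in tables], name="TCI")


def ntdci_frame(tables: list[ConnectednessTable]) -> pd.DataFrame:
    return pd.DataFrame(
        [t.ntdci for t in tables],
        index=[t.label for t in tables],
        columns=list(tables[0].labels),
    )


def classify_nodes(tables: list[ConnectednessTable]) -> list[NodeRole]:
    """Role by the sign of the time-mean NTDCI; purity by strict sign
    uniformity across every period (a zero anywhere breaks purity)."""
    if not tables:
        raise ValueError("need at least one period to classify nodes")
    ntdci = ntdci_frame(tables)
    roles = []
    for sid in ntdci.columns:
        path = ntdci[sid].to_numpy()
        mean = float(path.mean())
        role = "net transmitter" if mean > 0 else "net receiver"
        if np.all(path > 0):
            purity = "pure transmitter"
        elif np.all(path < 0):
            purity = "pure receiver"
        else:
            purity = "in-between"
        roles.append(NodeRole(series_id=sid, mean_ntdci=mean, role=role, purity=purity))
    return roles


def export_network(table: ConnectednessTable, min_edge: float = 0.0) -> list[Edge]:
    """Directed edge list oriented from net pairwise transmitter to receiver.

    For each unordered pair the edge runs from the series that transmits more
    than it receives, with weight |NPDCI|; pairs at or below ``min_edge``
    (including exactly balanced pairs) are dropped.
    """
    if min_edge < 0:
        raise ValueError("min_edge must be non-negative")
    labels = table.labels
    n = len(labels)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            w = table.npdci[i, j]
            if abs(w) <= min_edge or w == 0.0:
                continue
            if w > 0:  # i net-transmits to j
                edges.append(Edge(labels[i], labels[j], abs(w)))
            else:
                edges.append(Edge(labels[j], labels[i], abs(w)))
    return edges


def write_edge_list(edges: list[Edge], path) -> None:
    pd.DataFrame([(e.source, e.target, e.weight) for e in edges],
                 columns=["source", "target", "weight"]).to_csv(path, index=False, float_format="%.10g")


def write_dot(table: ConnectednessTable, edges: list[Edge], path) -> None:
    """Minimal DOT export: node size attr = mean NTDCI, color class = role."""
    lines = ["digraph connectedness {"]
    for sid, net in zip(table.labels, table.ntdci):
        color = "red" if net > 0 else "green"
        lines.append(f'  "{sid}" [ntdci="{net:.6g}", color={color}];')
    for e in edges:
        lines.append(f'  "{e.source}" -> "{e.target}" [weight="{e.weight:.6g}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def to_networkx(table: ConnectednessTable, min_edge: float = 0.0):
    """Weighted DiGraph with node attributes (mean NTDCI, role)."""
    import networkx as nx

    g = nx.DiGraph()
    for sid, net in zip(table.labels, table.ntdci):
        g.add_node(sid, ntdci=float(net), role="transmitter" if net > 0 else "receiver")
    for e in export_network(table, min_edge):
        g.add_edge(e.source, e.target, weight=e.weight)
    return g
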
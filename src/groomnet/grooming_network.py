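"""Directed percent-weight grooming matrices and individual network measures.

For each observation period the dyad counts become a directed matrix W with
w_ij = 100 * (scans where i groomed j) / (scans i and j were co-present),
so weights live on a 0-100 percent scale. Two individual measures follow:

* Vertex strength centrality, VSC_i = s_i / (N - 1) with s_i = sum_j w_ij —
  the mean percent of co-present scans an individual spent grooming a given
  group mate, standardized for group size.
* Deviation from edge weight disparity, DEWD_i = Y2_i - 1/(N - 1) with
  Y2_i = sum_j (w_ij / s_i)^2 — how far an individual's grooming departs
  from an even spread over all possible partners; 0 is perfectly even,
  (N-2)/(N-1) is total concentration on a single partner. Undefined for
  individuals that never groomed (s_i = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .study_data import (DyadCount, Individual, ObservationPeriod,
                         ValidationError)


@dataclass(frozen=True)
class GroomingMatrix:
    """Directed grooming weights for one period, members in lexicographic order."""

    period_code: str
    members: tuple[str, ...]
    W: np.ndarray  # N x N, percent scale, zero diagonal; NaN = missing dyad

    def __post_init__(self) -> None:
        n = len(self.members)
        if n < 2:
            raise ValidationError(
                f"matrix {self.period_code}: needs at least 2 members")
        if list(self.members) != sorted(self.members):
            raise ValidationError(
                f"matrix {self.period_code}: members must be sorted")
        if self.W.shape != (n, n):
            raise ValidationError(
                f"matrix {self.period_code}: W shape {self.W.shape} does "
                f"not match {n} members")
        with np.errstate(invalid="ignore"):
            if np.any((self.W < 0) | (self.W > 100)):
                raise ValidationError(
                    f"matrix {self.period_code}: weights outside [0, 100]")
        if np.any(np.diag(self.W) != 0):
            raise ValidationError(
                f"matrix {self.period_code}: nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.members)

    def index(self, member: str) -> int:
        try:
            return self.members.index(member)
        except ValueError:
            raise ValidationError(
                f"{member!r} is not a member of matrix "
                f"{self.period_code}") from None


def build_matrix(dyads: Sequence[DyadCount], period: ObservationPeriod,
                 on_zero_copresence: str = "error") -> GroomingMatrix:
    """Assemble the percent-weight matrix from ordered dyad counts.

    ``on_zero_copresence`` controls dyads whose denominator is zero:
    ``"error"`` (default) rejects the period, ``"missing"`` stores NaN so
    that downstream tables drop both individuals' records for the period.
    """
    if on_zero_copresence not in ("error", "missing"):
        raise ValidationError(
            f"unknown on_zero_copresence policy {on_zero_copresence!r}")
    members = tuple(sorted(period.members))
    idx = {m: i for i, m in enumerate(members)}
    n = len(members)
    W = np.full((n, n), np.nan)
    np.fill_diagonal(W, 0.0)
    for dyad in dyads:
        if dyad.actor not in idx or dyad.recipient not in idx:
            raise ValidationError(
                f"dyad {dyad.actor}->{dyad.recipient} outside period "
                f"{period.code} membership")
        if dyad.copresent_scans == 0:
            if on_zero_copresence == "error":
                raise ValidationError(
                    f"period {period.code}: dyad {dyad.actor}->"
                    f"{dyad.recipient} never co-present; weight undefined")
            continue  # leave NaN
        W[idx[dyad.actor], idx[dyad.recipient]] = (
            100.0 * dyad.groom_scans / dyad.copresent_scans)
    off_diag = ~np.eye(n, dtype=bool)
    if on_zero_copresence == "error" and np.isnan(W[off_diag]).any():
        missing = int(np.isnan(W[off_diag]).sum())
        raise ValidationError(
            f"period {period.code}: {missing} ordered dyad(s) without counts")
    return GroomingMatrix(period_code=period.code, members=members, W=W)


def _out_weights(m: GroomingMatrix, i: int) -> np.ndarray:
    row = np.delete(m.W[i], i)
    if np.isnan(row).any():
        raise ValidationError(
            f"matrix {m.period_code}: member {m.members[i]} has missing "
            "dyads; measures undefined")
    return row


def vertex_strength(m: GroomingMatrix, member: str) -> float:
    """s_i: sum of the member's outgoing percent weights."""
    return float(_out_weights(m, m.index(member)).sum())


def vsc(m: GroomingMatrix, member: str) -> float:
    """Vertex strength centrality s_i / (N - 1), on the percent scale."""
    i = m.index(member)
    return float(_out_weights(m, i).sum() / (m.n - 1))


def ewd(m: GroomingMatrix, member: str) -> float | None:
    """Edge weight disparity Y2_i, or None for a non-groomer (s_i = 0)."""
    i = m.index(member)
    row = _out_weights(m, i)
    s = row.sum()
    if s == 0:
        return None
    p = row / s
    return float(np.sum(p * p))


def dewd(m: GroomingMatrix, member: str) -> float | None:
    """Deviation from edge weight disparity, Y2_i - 1/(N-1); None if s_i = 0."""
    y2 = ewd(m, member)
    if y2 is None:
        return None
    return y2 - 1.0 / (m.n - 1)


def logit_dewd(values: Sequence[float], group_sizes: Sequence[int],
               squeeze: bool = True) -> np.ndarray:
    """Logit-transform DEWD values bounded in [0, (N-2)/(N-1)].

    Each value is first rescaled to [0, 1] by its own record's maximum
    (N-2)/(N-1) (group size varies across records), then — because exact 0
    and 1 have no logit — boundary-squeezed as y' = (y (M-1) + 0.5) / M over
    the M records, and finally mapped to log(y' / (1 - y')).
    """
    values = np.asarray(values, dtype=float)
    sizes = np.asarray(group_sizes, dtype=float)
    if values.shape != sizes.shape:
        raise ValidationError("values and group_sizes must align")
    if np.any(sizes < 3):
        raise ValidationError(
            "DEWD has zero range for N < 3; cannot rescale")
    top = (sizes - 2) / (sizes - 1)
    if np.any(values < -1e-12) or np.any(values - top > 1e-12):
        raise ValidationError("DEWD value outside [0, (N-2)/(N-1)]")
    y = np.clip(values / top, 0.0, 1.0)
    if squeeze:
        m_records = len(y)
        y = (y * (m_records - 1) + 0.5) / m_records
    elif np.any((y == 0) | (y == 1)):
        raise ValidationError(
            "exact boundary value; logit undefined without squeeze")
    return np.log(y / (1.0 - y))


MEASURE_COLUMNS = ["individual", "period_code", "n_group", "vertex_strength",
                   "vsc", "ewd", "dewd", "sex", "origin", "phc_infant",
                   "arrival_age_cat", "stability"]


def measures_table(matrices: Iterable[GroomingMatrix],
                   roster: Sequence[Individual],
                   periods: Sequence[ObservationPeriod]) -> pd.DataFrame:
    """One row per (individual, period): measures joined with covariates.

    EWD/DEWD are NaN for non-groomers, so the DEWD analysis has fewer data
    points than the VSC analysis. Individuals with missing dyads (zero
    co-presence under the "missing" policy) are dropped for that period.
    """
    by_id = {ind.id: ind for ind in roster}
    by_code = {p.code: p for p in periods}
    rows: list[dict[str, object]] = []
    for m in matrices:
        period = by_code.get(m.period_code)
        if period is None:
            raise ValidationError(f"matrix {m.period_code}: unknown period")
        for member in m.members:
            ind = by_id.get(member)
            if ind is None:
                raise ValidationError(
                    f"matrix {m.period_code}: member {member!r} missing "
                    "from roster")
            i = m.index(member)
            row_w = np.delete(m.W[i], i)
            col_w = np.delete(m.W[:, i], i)
            if np.isnan(row_w).any() or np.isnan(col_w).any():
                continue  # dyad missing: drop this individual's record
            s = float(row_w.sum())
            y2 = dewd_val = math.nan
            if s > 0:
                p = row_w / s
                y2 = float(np.sum(p * p))
                dewd_val = y2 - 1.0 / (m.n - 1)
            rows.append({
                "individual": member, "period_code": m.period_code,
                "n_group": m.n, "vertex_strength": s, "vsc": s / (m.n - 1),
                "ewd": y2, "dewd": dewd_val,
                "sex": ind.sex, "origin": ind.origin,
                "phc_infant": ind.phc_infant,
                "arrival_age_cat": ind.arrival_age_cat,
                "stability": period.stability,
            })
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def to_graph(m: GroomingMatrix,
             roster: Sequence[Individual] | None = None) -> nx.DiGraph:
    """NetworkX view: nodes are individuals, directed edges carry weights."""
    g = nx.DiGraph(period_code=m.period_code)
    attrs = {ind.id: ind for ind in roster} if roster else {}
    for member in m.members:
        ind = attrs.get(member)
        if ind is not None:
            g.add_node(member, sex=ind.sex, origin=ind.origin)
        else:
            g.add_node(member)
    for i, a in enumerate(m.members):
        for j, b in enumerate(m.members):
            if i != j and m.W[i, j] > 0:
                g.add_edge(a, b, weight=float(m.W[i, j]))
    return g


def export_network(m: GroomingMatrix, fmt: str, path: str | Path,
                   roster: Sequence[Individual] | None = None) -> Path:
    """Write a period network as ``edge_list`` CSV, ``graphml`` or ``matrix`` CSV.

    The edge list emits only nonzero edges; GraphML and the matrix CSV are
    lossless and round-trip through :func:`import_network`.
    """
    path = Path(path)
    if fmt == "edge_list":
        rows = [
            {"period_code": m.period_code, "actor": a, "recipient": b,
             "weight_percent": float(m.W[i, j])}
            for i, a in enumerate(m.members)
            for j, b in enumerate(m.members)
            if i != j and m.W[i, j] > 0
        ]
        pd.DataFrame(rows, columns=["period_code", "actor", "recipient",
                                    "weight_percent"]).to_csv(path,
                                                              index=False)
    elif fmt == "graphml":
        nx.write_graphml(to_graph(m, roster), path)
    elif fmt == "matrix":
        pd.DataFrame(m.W, index=list(m.members),
                     columns=list(m.members)).to_csv(path)
    else:
        raise ValidationError(f"unknown export format {fmt!r}")
    return path


def import_network(fmt: str, path: str | Path, period_code: str = "",
                   members: Sequence[str] | None = None) -> GroomingMatrix:
    """Read a network export back into a :class:`GroomingMatrix`.

    The edge-list format does not carry isolated members, so ``members``
    must be supplied for an exact round trip.
    """
    path = Path(path)
    if fmt == "edge_list":
        frame = pd.read_csv(path)
        if members is None:
            members = sorted(set(frame["actor"]) | set(frame["recipient"]))
        if not period_code and len(frame):
            period_code = str(frame["period_code"].iloc[0])
        members = tuple(sorted(members))
        idx = {m: i for i, m in enumerate(members)}
        W = np.zeros((len(members), len(members)))
        for _, row in frame.iterrows():
            W[idx[row["actor"]], idx[row["recipient"]]] = row["weight_percent"]
        return GroomingMatrix(period_code=period_code, members=members, W=W)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        members = tuple(sorted(g.nodes))
        idx = {m: i for i, m in enumerate(members)}
        W = np.zeros((len(members), len(members)))
        for a, b, data in g.edges(data=True):
            W[idx[a], idx[b]] = float(data.get("weight", 0.0))
        return GroomingMatrix(
            period_code=period_code or g.graph.get("period_code", ""),
            members=members, W=W)
    if fmt == "matrix":
        frame = pd.read_csv(path, index_col=0)
        members = tuple(str(m) for m in frame.index)
        return GroomingMatrix(period_code=period_code, members=members,
                              W=frame.to_numpy(dtype=float))
    raise ValidationError(f"unknown import format {fmt!r}")
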
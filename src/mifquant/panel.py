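"""Elution-tolerance matrices and sequence-position assignment for TSA panels.

Sequential tyramide multiplexing strips the antibody between staining
rounds with heat elution; each additional elution cycle can degrade (or
occasionally enhance) an epitope's thresholded MFI.  Measuring each
marker's % MFI change at every candidate position yields a tolerance
matrix; the panel order is then the bijection marker -> position that
maximizes the summed % MFI retention.

Because detection alternates anti-mouse and anti-rabbit secondaries, a
practical panel usually also requires consecutive positions to alternate
host species; ``assign_positions`` supports that as an explicit constraint.
The optimizer is an exhaustive search (panels are small, n <= 8), and the
unconstrained solution is certified against the Hungarian-algorithm
optimum.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

MAX_EXHAUSTIVE = 8

HOSTS = ("mouse", "rabbit")


class PanelError(ValueError):
    pass


@dataclass
class ToleranceMatrix:
    """% change in thresholded MFI per marker x sequence position.

    ``values[m, k]`` is the percent change at position k+1 relative to
    position 1, so the first column is identically zero.
    """

    markers: list[str]
    hosts: list[str]
    values: np.ndarray
    clones: list[str] | None = None
    raw_mfi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n != len(self.markers) or len(self.hosts) != n:
            raise PanelError("markers, hosts and value rows must align")
        if k < 2:
            raise PanelError("need at least 2 positions")
        if not np.allclose(self.values[:, 0], 0.0):
            raise PanelError("position-1 values must all be 0 (reference position)")
        for h in self.hosts:
            if h not in HOSTS:
                raise PanelError(f"unknown host {h!r}; expected one of {HOSTS}")

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    def host_of(self, marker: str) -> str:
        return self.hosts[self.markers.index(marker)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.markers,
                          columns=[f"position_{k + 1}" for k in range(self.n_positions)])
        df.insert(0, "host", self.hosts)
        if self.clones is not None:
            df.insert(0, "clone", self.clones)
        df.index.name = "marker"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ToleranceMatrix":
        df = pd.read_csv(path, index_col="marker")
        pos_cols = [c for c in df.columns if c.startswith("position_")]
        return cls(
            markers=list(df.index),
            hosts=list(df["host"]),
            values=df[pos_cols].to_numpy(float),
            clones=list(df["clone"]) if "clone" in df.columns else None,
        )


def percent_change_matrix(raw_mfi, markers, hosts, clones=None) -> ToleranceMatrix:
    """Tolerance matrix from raw thresholded MFIs.

    ``value[m, k] = 100 * (mfi[m, k] - mfi[m, 0]) / mfi[m, 0]``; position 1
    is the non-eluted reference and must be positive.
    """
    raw = np.asarray(raw_mfi, dtype=float)
    if raw.ndim != 2:
        raise PanelError("raw_mfi must be a marker x position matrix")
    if np.any(raw <= 0):
        bad = [markers[i] for i in np.unique(np.argwhere(raw <= 0)[:, 0])]
        raise PanelError(f"raw MFIs must be positive (offending marker(s): {bad})")
    values = 100.0 * (raw - raw[:, :1]) / raw[:, :1]
    return ToleranceMatrix(list(markers), list(hosts), values,
                           clones=list(clones) if clones is not None else None,
                           raw_mfi=raw)


@dataclass
class PanelAssignment:
    """Optimal marker -> position bijection with its objective value."""

    positions: dict[str, int]
    objective: float
    constraint: str
    certified: bool = False

    def ordered_markers(self) -> list[str]:
        """Markers in staining order (position 1 first)."""
        return [m for m, _ in sorted(self.positions.items(), key=lambda kv: kv[1])]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "positions": self.positions,
                "objective": self.objective,
                "constraint": self.constraint,
                "certified": self.certified,
            }, fh, indent=1)


def _alternates(hosts_in_order: list[str]) -> bool:
    return all(a != b for a, b in zip(hosts_in_order, hosts_in_order[1:]))


def assign_positions(tol: ToleranceMatrix, constraint: str = "none",
                     ) -> PanelAssignment:
    """Maximize summed % MFI retention over marker -> position bijections.

    ``constraint='host_alternating'`` restricts the search to orders where
    consecutive positions alternate antibody host species.  Ties are broken
    by lexicographic marker order (markers sorted by name take the earliest
    position permutation).  Exhaustive search; the unconstrained result is
    certified against ``scipy.optimize.linear_sum_assignment``.
    """
    if constraint not in ("none", "host_alternating"):
        raise PanelError(f"unknown constraint {constraint!r}")
    n = len(tol.markers)
    if n != tol.n_positions:
        raise PanelError(
            f"{n} markers vs {tol.n_positions} positions: need a square problem"
        )
    if n > MAX_EXHAUSTIVE:
        raise PanelError(f"exhaustive search supports n <= {MAX_EXHAUSTIVE}")

    order = sorted(range(n), key=lambda i: tol.markers[i])
    if constraint == "host_alternating":
        counts = {h: tol.hosts.count(h) for h in HOSTS}
        if abs(counts["mouse"] - counts["rabbit"]) > 1:
            raise PanelError(
                "host_alternating is infeasible: host counts "
                f"{counts} differ by more than 1"
            )

    best_obj, best_perm = -np.inf, None
    # perm[j] = 0-based position of the j-th marker in sorted-name order;
    # itertools yields position tuples lexicographically, so keeping the
    # first strict improvement realises the documented tie-break.
    for perm in itertools.permutations(range(n)):
        if constraint == "host_alternating":
            host_at = [None] * n
            for j, p in enumerate(perm):
                host_at[p] = tol.hosts[order[j]]
            if not _alternates(host_at):
                continue
        obj = sum(tol.values[order[j], perm[j]] for j in range(n))
        if obj > best_obj + 1e-12:
            best_obj, best_perm = obj, perm
    if best_perm is None:
        raise PanelError("no feasible assignment under the given constraint")

    positions = {tol.markers[order[j]]: best_perm[j] + 1 for j in range(n)}
    certified = False
    if constraint == "none":
        row, col = linear_sum_assignment(tol.values, maximize=True)
        lsa_obj = float(tol.values[row, col].sum())
        if not np.isclose(lsa_obj, best_obj):
            raise AssertionError(
                f"exhaustive optimum {best_obj} disagrees with "
                f"linear-sum-assignment optimum {lsa_obj}"
            )
        certified = True
    return PanelAssignment(positions, float(best_obj), constraint, certified)
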
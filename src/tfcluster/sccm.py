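"""Shared coexpression connectivity matrix (SCCM).

The SCCM is a symmetric p x p integer matrix A over TFs whose entry
a_ij = |G_i ∩ G_j| counts the coexpressed genes shared by the
neighborhoods of TFs y_i and y_j (the connectivity n_c). It is a
shared-nearest-neighbor-style graph: two TFs are strongly connected not
because their own profiles correlate, but because they sit in the same
genome-wide coexpression context. The matrix is stored sparse and
upper-triangular; zero intersections are never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import scipy.io
import scipy.sparse

from .coexpression import Neighborhood
from .io import write_table

__all__ = [
    "SCCM",
    "ConnectivityStats",
    "build_sccm",
    "connectivity_stats",
    "export_sccm",
    "load_sccm_edges",
]


@dataclass(frozen=True)
class SCCM:
    """Sparse symmetric connectivity matrix.

    ``entries`` maps index pairs ``(i, j)`` with ``i < j`` to the
    positive integer connectivity; an absent pair means zero. The
    diagonal is undefined and never stored.
    """

    tf_ids: tuple
    omega: int
    entries: dict

    def __post_init__(self):
        index = {t: i for i, t in enumerate(self.tf_ids)}
        if len(index) != len(self.tf_ids):
            raise ValueError("duplicate TF ids in SCCM")
        for (i, j), v in self.entries.items():
            if not (0 <= i < j < len(self.tf_ids)):
                raise ValueError(f"invalid index pair ({i}, {j})")
            if not (1 <= v <= self.omega):
                raise ValueError(
                    f"connectivity {v} out of range [1, omega={self.omega}]"
                )
        object.__setattr__(self, "_index", index)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_nonzero(self) -> int:
        return len(self.entries)

    def get(self, tf_a: str, tf_b: str) -> int:
        """Connectivity n_c between two TFs (0 when no shared genes)."""
        i, j = self._index[tf_a], self._index[tf_b]
        if i == j:
            raise ValueError(f"diagonal lookup for {tf_a!r} is undefined")
        if i > j:
            i, j = j, i
        return self.entries.get((i, j), 0)

    def id_pairs(self) -> Iterable:
        """Yield ``(tf_a, tf_b, n_c)`` with the pair in lexicographic order."""
        for (i, j), v in self.entries.items():
            a, b = self.tf_ids[i], self.tf_ids[j]
            if a > b:
                a, b = b, a
            yield a, b, v


@dataclass(frozen=True)
class ConnectivityStats:
    """Mean and sample standard deviation of the non-zero connectivities;
    the basis of every significance threshold."""

    mu: float
    delta: float
    n_nonzero: int


def build_sccm(neighborhoods: Sequence[Neighborhood]) -> SCCM:
    """Count shared neighborhood members for every TF pair.

    Rank order inside a neighborhood is irrelevant: connectivity is a
    pure set intersection.
    """
    nbs = list(neighborhoods)
    if len(nbs) < 2:
        raise ValueError("need at least 2 neighborhoods")
    tf_ids = [n.tf_id for n in nbs]
    if len(set(tf_ids)) != len(tf_ids):
        dup = next(t for t in tf_ids if tf_ids.count(t) > 1)
        raise ValueError(f"duplicated TF id {dup!r} across neighborhoods")
    omegas = {len(n) for n in nbs}
    if len(omegas) != 1:
        raise ValueError(f"neighborhoods have differing sizes {sorted(omegas)}")
    omega = omegas.pop()
    sets = [n.member_set for n in nbs]
    entries: dict = {}
    for i in range(len(nbs)):
        si = sets[i]
        for j in range(i + 1, len(nbs)):
            c = len(si & sets[j])
            if c:
                entries[(i, j)] = c
    return SCCM(tf_ids=tuple(tf_ids), omega=omega, entries=entries)


def connectivity_stats(sccm: SCCM) -> ConnectivityStats:
    """mu / delta over the stored (non-zero) entries; delta is the sample
    (n-1) standard deviation, defined as 0 for a single entry."""
    vals = np.array(sorted(sccm.entries.values()), dtype=float)
    if vals.size == 0:
        raise ValueError(
            "SCCM has no non-zero connectivities; consider a larger omega "
            "or a compendium with more samples"
        )
    mu = float(vals.mean())
    delta = 0.0 if vals.size == 1 else float(vals.std(ddof=1))
    return ConnectivityStats(mu=mu, delta=delta, n_nonzero=int(vals.size))


def export_sccm(sccm: SCCM, path: Union[str, Path], format: str = "edge-list-tsv") -> None:
    """Write the SCCM as a sorted edge list TSV or as Matrix Market
    symmetric integer coordinate format."""
    path = Path(path)
    if format == "edge-list-tsv":
        rows = [
            {"tf_a": a, "tf_b": b, "n_c": v}
            for a, b, v in sorted(sccm.id_pairs())
        ]
        write_table(rows, path, columns=("tf_a", "tf_b", "n_c"))
    elif format == "mtx":
        p = sccm.n_tfs
        if sccm.entries:
            ii, jj = zip(*sccm.entries.keys())
            vv = [sccm.entries[k] for k in sccm.entries]
        else:
            ii, jj, vv = (), (), ()
        # lower triangle (row >= col) as mmwrite expects for symmetric
        mat = scipy.sparse.coo_matrix(
            (np.asarray(vv, dtype=np.int64), (np.asarray(jj, int), np.asarray(ii, int))),
            shape=(p, p),
        )
        scipy.io.mmwrite(str(path), mat, symmetry="symmetric", field="integer")
    else:
        raise ValueError(f"unknown export format {format!r}")


def load_sccm_edges(path: Union[str, Path], tf_ids: Sequence[str], omega: int) -> SCCM:
    """Rebuild an SCCM from an edge-list TSV written by :func:`export_sccm`."""
    index = {t: i for i, t in enumerate(tf_ids)}
    entries: dict = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        a, b, v = line.split("\t")
        i, j = index[a], index[b]
        if i > j:
            i, j = j, i
        entries[(i, j)] = int(v)
    return SCCM(tf_ids=tuple(tf_ids), omega=omega, entries=entries)
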
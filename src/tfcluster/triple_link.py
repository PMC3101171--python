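"""Triple-Link decomposition of the SCCM into ordered TF clusters.

The heuristic seeds each cluster at the available TF pair with the
maximal connectivity n_c, then greedily admits candidates whose
strongest links into the cluster clear a descending ladder of
significance thresholds tau_k = mu + theta_k * delta, where mu and delta
summarize the non-zero connectivities of the full matrix. A third member
needs two significant links (> tau1, > tau2 on its two strongest); every
later member needs three (> tau1, > tau2, > tau3 on its three
strongest). All comparisons are strict. When no candidate qualifies the
cluster is extracted, its members leave the pool, and seeding repeats
until no available pair exceeds tau1 — so earlier clusters are the more
significant ones by construction.

The mapping of the three thresholds onto individual links is this
implementation's reading of the rule: the strictest threshold guards the
strongest required link, which uses all three theta and degrades
gracefully as stringency is relaxed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .sccm import SCCM, ConnectivityStats, connectivity_stats

__all__ = [
    "TripleLinkParams",
    "JoinAudit",
    "TFCluster",
    "ClusteringResult",
    "thresholds",
    "qualifies",
    "find_seed_pair",
    "grow_cluster",
    "decompose",
]

#: Empirical envelopes for the stringency multipliers.
THETA_ENVELOPES = ((1.5, 2.5), (1.0, 2.0), (0.5, 1.5))


@dataclass(frozen=True)
class TripleLinkParams:
    """Stringency multipliers theta1 > theta2 > theta3 (strict).

    Defaults (2.0, 1.5, 1.0) are the midpoints of the empirical ranges
    theta1 in [1.5, 2.5], theta2 in [1.0, 2.0], theta3 in [0.5, 1.5];
    values outside the envelopes warn but are accepted.
    """

    theta1: float = 2.0
    theta2: float = 1.5
    theta3: float = 1.0

    def __post_init__(self):
        if not (self.theta1 > self.theta2 > self.theta3):
            raise ValueError(
                f"theta1 > theta2 > theta3 is required, got "
                f"({self.theta1}, {self.theta2}, {self.theta3})"
            )
        for name, th, (lo, hi) in zip(
            ("theta1", "theta2", "theta3"),
            (self.theta1, self.theta2, self.theta3),
            THETA_ENVELOPES,
        ):
            if not (lo <= th <= hi):
                warnings.warn(
                    f"{name}={th} is outside the empirical envelope [{lo}, {hi}]",
                    UserWarning,
                    stacklevel=2,
                )

    @property
    def thetas(self) -> tuple:
        return (self.theta1, self.theta2, self.theta3)


@dataclass(frozen=True)
class JoinAudit:
    """Record of why one TF entered a cluster; re-checkable against the
    SCCM and thresholds.

    ``witness_links`` are the candidate's strongest links to the members
    present at join time, as ``(member_id, n_c)`` sorted by descending
    n_c — exactly the links the rule compared against ``taus_required``.
    """

    tf_id: str
    rule: str  # "seed", "pair", or "triple"
    witness_links: tuple
    taus_required: tuple

    def replay(self) -> bool:
        """Re-evaluate the recorded decision: every witness link must
        strictly exceed its matching threshold."""
        if len(self.witness_links) < len(self.taus_required):
            return False
        return all(
            link > tau
            for (_, link), tau in zip(self.witness_links, self.taus_required)
        )


@dataclass(frozen=True)
class TFCluster:
    """One extracted cluster: seed pair first, then members in join order."""

    cluster_id: int
    members: tuple
    seed: tuple  # (tf_a, tf_b, n_c)
    audits: tuple  # one JoinAudit per member beyond the seed pair

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a cluster has at least 2 members")
        if tuple(self.members[:2]) != tuple(self.seed[:2]):
            raise ValueError("seed pair must open the member list")

    @property
    def seed_connectivity(self) -> int:
        return self.seed[2]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusteringResult:
    """Ordered clusters plus the TFs never placed in any cluster."""

    clusters: tuple
    unclustered: tuple
    stats_used: ConnectivityStats
    params_used: TripleLinkParams
    taus: tuple

    def labels(self) -> dict:
        """tf_id -> cluster_id, or 0 for unclustered."""
        out = {t: 0 for t in self.unclustered}
        for cl in self.clusters:
            for t in cl.members:
                out[t] = cl.cluster_id
        return out

    def to_dict(self) -> dict:
        return {
            "stats_used": {
                "mu": self.stats_used.mu,
                "delta": self.stats_used.delta,
                "n_nonzero": self.stats_used.n_nonzero,
            },
            "params_used": {
                "theta1": self.params_used.theta1,
                "theta2": self.params_used.theta2,
                "theta3": self.params_used.theta3,
            },
            "taus": list(self.taus),
            "clusters": [
                {
                    "cluster_id": cl.cluster_id,
                    "members": list(cl.members),
                    "seed": {"tf_a": cl.seed[0], "tf_b": cl.seed[1], "n_c": cl.seed[2]},
                    "audits": [
                        {
                            "tf_id": a.tf_id,
                            "rule": a.rule,
                            "witness_links": [
                                {"member": m, "n_c": v} for m, v in a.witness_links
                            ],
                            "taus_required": list(a.taus_required),
                        }
                        for a in cl.audits
                    ],
                }
                for cl in self.clusters
            ],
            "unclustered": list(self.unclustered),
        }


def thresholds(stats: ConnectivityStats, params: TripleLinkParams) -> tuple:
    """tau_k = mu + theta_k * delta for k = 1, 2, 3."""
    return tuple(stats.mu + th * stats.delta for th in params.thetas)


def qualifies(
    candidate: str,
    members: Sequence[str],
    sccm: SCCM,
    taus: tuple,
) -> tuple:
    """Pure join predicate.

    With two members present the candidate's two links, sorted
    descending, must satisfy link1 > tau1 and link2 > tau2; with three or
    more members its three strongest links must beat (tau1, tau2, tau3).
    Returns ``(ok, audit_or_None)``.
    """
    members = list(members)
    if candidate in members:
        raise ValueError(f"candidate {candidate!r} is already a member")
    links = sorted(
        ((m, sccm.get(candidate, m)) for m in members),
        key=lambda mv: (-mv[1], mv[0]),
    )
    if len(members) == 2:
        need = taus[:2]
        rule = "pair"
    else:
        need = taus[:3]
        rule = "triple"
    witness = tuple(links[: len(need)])
    if len(witness) < len(need):
        return False, None
    if all(link > tau for (_, link), tau in zip(witness, need)):
        return True, JoinAudit(
            tf_id=candidate, rule=rule, witness_links=witness, taus_required=tuple(need)
        )
    return False, None


def find_seed_pair(sccm: SCCM, available: set, tau1: float) -> Optional[tuple]:
    """The available pair with maximal n_c, provided n_c > tau1 strictly;
    ties broken by lexicographic (tf_a, tf_b). None signals termination."""
    best = None
    for a, b, v in sccm.id_pairs():
        if a not in available or b not in available:
            continue
        if v <= tau1:
            continue
        key = (-v, a, b)
        if best is None or key < best[0]:
            best = (key, (a, b, v))
    return best[1] if best else None


def grow_cluster(
    seed: tuple,
    sccm: SCCM,
    available: set,
    taus: tuple,
    cluster_id: int = 1,
) -> TFCluster:
    """Grow a cluster from a seed pair until no candidate qualifies.

    Among qualifying candidates each round, the one with the greatest
    total connectivity to the current members joins (lexicographic
    tie-break), so growth is deterministic.
    """
    a, b, nc = seed
    members = [a, b]
    audits = []
    pool = set(available) - {a, b}
    while True:
        best = None
        for cand in pool:
            ok, audit = qualifies(cand, members, sccm, taus)
            if not ok:
                continue
            total = sum(sccm.get(cand, m) for m in members)
            key = (-total, cand)
            if best is None or key < best[0]:
                best = (key, cand, audit)
        if best is None:
            break
        _, cand, audit = best
        members.append(cand)
        audits.append(audit)
        pool.discard(cand)
    return TFCluster(
        cluster_id=cluster_id,
        members=tuple(members),
        seed=(a, b, nc),
        audits=tuple(audits),
    )


def decompose(
    sccm: SCCM,
    params: TripleLinkParams = None,
    stats: ConnectivityStats = None,
    recompute_stats: bool = False,
) -> ClusteringResult:
    """Repeated seed-and-grow until no available pair is significant.

    mu and delta are computed once from the full matrix (they are
    properties of the SCCM, and keeping them fixed makes extraction
    order well defined). ``recompute_stats=True`` re-derives them from
    the surviving entries before each seeding round instead.
    ``stats`` may be supplied to decouple thresholding from the matrix.
    """
    params = params or TripleLinkParams()
    if not sccm.entries:
        raise ValueError("cannot decompose an SCCM with no non-zero connectivities")
    base_stats = stats if stats is not None else connectivity_stats(sccm)
    taus = thresholds(base_stats, params)
    available = set(sccm.tf_ids)
    clusters = []
    while True:
        if recompute_stats and stats is None:
            surviving = [
                v
                for (i, j), v in sccm.entries.items()
                if sccm.tf_ids[i] in available and sccm.tf_ids[j] in available
            ]
            if not surviving:
                break
            mu = float(np.mean(surviving))
            delta = 0.0 if len(surviving) == 1 else float(np.std(surviving, ddof=1))
            round_stats = ConnectivityStats(mu, delta, len(surviving))
            taus = thresholds(round_stats, params)
        seed = find_seed_pair(sccm, available, taus[0])
        if seed is None:
            break
        cluster = grow_cluster(seed, sccm, available, taus, cluster_id=len(clusters) + 1)
        clusters.append(cluster)
        available -= set(cluster.members)
    final_taus = thresholds(base_stats, params)
    unclustered = tuple(t for t in sccm.tf_ids if t in available)
    return ClusteringResult(
        clusters=tuple(clusters),
        unclustered=unclustered,
        stats_used=base_stats,
        params_used=params,
        taus=final_taus,
    )
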
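"""Reconstruction of parental embryonic cell lineages from shared mutations.

Mutations shared by two or more siblings are agglomerated: at each step the
pair of (pseudo-)mutations whose carrier sets co-occur most improbably
under independence — an upper-tail binomial test on the overlap — is merged
into one pseudo-mutation carried by the union of offspring, provided their
known parental origins do not conflict.  Merging stops when no remaining
pair beats the p-value threshold.  The resulting clusters are the parental
lineages; randomisation utilities score shuffled assignments for biological
concordance (an offspring may belong to at most one paternal and one
maternal lineage).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SharingMatrix",
    "Lineage",
    "LineagePartition",
    "cooccurrence_pvalue",
    "reconstruct_lineages",
    "check_concordance",
    "reassignment_validation",
    "partition_to_newick",
]


@dataclass
class SharingMatrix:
    """Binary presence/absence of shared mutations across offspring."""

    mutation_ids: list[str]
    offspring_ids: list[str]
    matrix: np.ndarray  # (n_mutations, n_offspring) of {0, 1}
    origins: dict[str, str] = field(default_factory=dict)  # id -> paternal|maternal

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.mutation_ids), len(self.offspring_ids)):
            raise ValueError("matrix shape does not match id lists")
        if (self.matrix.sum(axis=1) < 2).any():
            raise ValueError("every shared mutation needs >= 2 carriers")

    @classmethod
    def from_carrier_sets(
        cls,
        carriers: dict[str, set[str]],
        offspring_ids: Sequence[str],
        origins: Optional[dict[str, str]] = None,
    ) -> "SharingMatrix":
        mids = sorted(carriers)
        oids = list(offspring_ids)
        idx = {o: j for j, o in enumerate(oids)}
        mat = np.zeros((len(mids), len(oids)), dtype=bool)
        for i, mid in enumerate(mids):
            for o in carriers[mid]:
                mat[i, idx[o]] = True
        return cls(mids, oids, mat, dict(origins or {}))


@dataclass
class Lineage:
    parent: str  # paternal | maternal | unknown
    mutation_ids: list[str]
    carriers: set[str]


@dataclass
class LineagePartition:
    lineages: list[Lineage]
    residual_offspring: set[str]
    n_offspring: int


def cooccurrence_pvalue(n_offspring: int, carriers_a: set, carriers_b: set) -> float:
    """Upper-tail probability of the observed carrier overlap under
    independent sharing: with frequencies ``p = |A|/n`` and ``q = |B|/n``,
    ``P(X >= |A & B|)`` for ``X ~ Binomial(n, p q)``."""
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    if not carriers_a or not carriers_b:
        raise ValueError("carrier sets must be non-empty")
    p = len(carriers_a) / n_offspring
    q = len(carriers_b) / n_offspring
    k = len(set(carriers_a) & set(carriers_b))
    return float(stats.binom.sf(k - 1, n_offspring, p * q))


def _compatible(origin_a: str, origin_b: str) -> bool:
    return origin_a == "unknown" or origin_b == "unknown" or origin_a == origin_b


def reconstruct_lineages(
    matrix: SharingMatrix,
    p_threshold: float = 0.05,
    update_frequencies: bool = True,
) -> LineagePartition:
    """Iteratively agglomerate shared mutations into parental lineages.

    Ties on the p-value break towards the lexicographically smallest pair
    of cluster keys, making the procedure deterministic.  With
    ``update_frequencies`` the binomial frequencies are recomputed from the
    current pseudo-mutation carrier sets after every merge; otherwise each
    cluster keeps the largest initial member frequency.
    """
    n = len(matrix.offspring_ids)
    clusters: dict[str, dict] = {}
    for i, mid in enumerate(matrix.mutation_ids):
        carriers = {o for o, bit in zip(matrix.offspring_ids, matrix.matrix[i]) if bit}
        clusters[mid] = {
            "members": [mid],
            "carriers": carriers,
            "origin": matrix.origins.get(mid, "unknown"),
            "freq0": len(carriers) / n,
        }

    while len(clusters) > 1:
        best = None
        for ka, kb in itertools.combinations(sorted(clusters), 2):
            ca, cb = clusters[ka], clusters[kb]
            if not _compatible(ca["origin"], cb["origin"]):
                continue
            if update_frequencies:
                p = cooccurrence_pvalue(n, ca["carriers"], cb["carriers"])
            else:
                k = len(ca["carriers"] & cb["carriers"])
                p = float(stats.binom.sf(k - 1, n, ca["freq0"] * cb["freq0"]))
            if best is None or p < best[0]:
                best = (p, ka, kb)
        if best is None or best[0] >= p_threshold:
            break
        _, ka, kb = best
        ca, cb = clusters.pop(ka), clusters.pop(kb)
        origin = ca["origin"] if ca["origin"] != "unknown" else cb["origin"]
        merged_key = min(ka, kb)
        clusters[merged_key] = {
            "members": ca["members"] + cb["members"],
            "carriers": ca["carriers"] | cb["carriers"],
            "origin": origin,
            "freq0": max(ca["freq0"], cb["freq0"]),
        }

    lineages = [
        Lineage(
            parent=c["origin"],
            mutation_ids=sorted(c["members"]),
            carriers=set(c["carriers"]),
        )
        for _, c in sorted(clusters.items())
    ]
    covered = set().union(*(l.carriers for l in lineages)) if lineages else set()
    residual = set(matrix.offspring_ids) - covered
    return LineagePartition(
        lineages=lineages, residual_offspring=residual, n_offspring=n
    )


def check_concordance(partition: LineagePartition) -> bool:
    """True iff no offspring belongs to two lineages of the same parent
    (lineages of unknown parent are not constrained)."""
    for parent in ("paternal", "maternal"):
        seen: set[str] = set()
        for lin in partition.lineages:
            if lin.parent != parent:
                continue
            if seen & lin.carriers:
                return False
            seen |= lin.carriers
    return True


def _concordant_bool(
    carrier_mat: np.ndarray, cluster_members: list[np.ndarray], parents: list[str]
) -> bool:
    for want in ("paternal", "maternal"):
        cover = np.zeros(carrier_mat.shape[1], dtype=int)
        for members, parent in zip(cluster_members, parents):
            if parent != want:
                continue
            cover += carrier_mat[members].any(axis=0)
        if (cover > 1).any():
            return False
    return True


def reassignment_validation(
    matrix: SharingMatrix,
    partition: LineagePartition,
    mode: str = "shuffle_lineage_labels",
    n_reps: int = 10_000,
    seed: int = 0,
    cluster_size_range: tuple[int, int] = (2, 10),
) -> int:
    """Count biologically concordant replicates under random reassignment.

    ``shuffle_lineage_labels`` permutes mutations across the existing
    lineage slots (sizes and parent labels fixed); ``random_cluster_sizes``
    draws fresh clusterings with cluster sizes in ``cluster_size_range``,
    labelling each cluster by the majority known origin of its members.
    Deterministic for a fixed seed.
    """
    if mode not in ("shuffle_lineage_labels", "random_cluster_sizes"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(partition.lineages) < 2:
        raise ValueError("need at least two lineages to randomise")
    rng = np.random.default_rng(seed)
    mat = matrix.matrix
    mid_index = {m: i for i, m in enumerate(matrix.mutation_ids)}
    n_mut = len(matrix.mutation_ids)
    origins = [matrix.origins.get(m, "unknown") for m in matrix.mutation_ids]

    concordant = 0
    if mode == "shuffle_lineage_labels":
        sizes = [len(l.mutation_ids) for l in partition.lineages]
        parents = [l.parent for l in partition.lineages]
        for _ in range(n_reps):
            perm = rng.permutation(n_mut)
            members, start = [], 0
            for s in sizes:
                members.append(perm[start : start + s])
                start += s
            if _concordant_bool(mat, members, parents):
                concordant += 1
    else:
        lo, hi = cluster_size_range
        for _ in range(n_reps):
            perm = rng.permutation(n_mut)
            members, start = [], 0
            while start < n_mut:
                s = int(rng.integers(lo, hi + 1))
                members.append(perm[start : start + s])
                start += s
            parents = []
            for mem in members:
                labs = [origins[i] for i in mem if origins[i] != "unknown"]
                if labs:
                    pat = labs.count("paternal")
                    parents.append("paternal" if pat * 2 >= len(labs) else "maternal")
                else:
                    parents.append("paternal")
            if _concordant_bool(mat, members, parents):
                concordant += 1
    return concordant


def partition_to_newick(partition: LineagePartition) -> str:
    """Star-tree-per-lineage newick string for quick visualisation."""
    stars = []
    for i, lin in enumerate(partition.lineages):
        leaves = ",".join(sorted(lin.carriers))
        stars.append(f"({leaves})L{i}_{lin.parent}")
    residual = ",".join(sorted(partition.residual_offspring))
    if residual:
        stars.append(f"({residual})residual")
    return "(" + ",".join(stars) + ");"
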
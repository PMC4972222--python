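"""Clone (ramet/genet) identification and probability of identity.

Patches of a clonal plant sampled in the field may belong to the same
genet.  Near-identical multilocus genotypes are flagged with the Lynch
band-sharing distance: per locus the similarity of the two allele *sets*
is ``s = 2|A . B| / (|A| + |B|)`` (a heterozygote contributes two
distinct alleles, a homozygote one) and the distance is ``1 - mean(s)``
over the loci typed in both individuals.  Pairs below a distance
threshold (0.05 by default) are merged by single linkage into genets and
one representative patch per genet is drawn at random.

The multilocus probability of identity quantifies how likely two
*independent* individuals are to share a genotype by chance:
``PI_l = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2`` per locus, multiplied
across loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ssrherit.genotype_io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeTable,
)


def n_unordered_pairs(n: int) -> int:
    """Number of unordered pairwise comparisons among ``n`` items, C(n, 2)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


@dataclass
class DistanceMatrix:
    """Symmetric pairwise genetic distances in [0, 1] with zero diagonal.

    ``n_usable_loci`` counts, per pair, the loci non-missing in both
    members; pairs with no shared typed locus carry distance ``nan`` and
    are treated as distinct genotypes by :func:`assign_clones`.
    """

    ids: list[str]
    values: np.ndarray
    n_usable_loci: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        finite = np.isfinite(v)
        if not np.array_equal(v, v.T) and not np.allclose(
            v[finite & finite.T], v.T[finite & finite.T]
        ):
            raise ValueError("distance matrix is not symmetric")
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValueError("distances outside [0, 1]")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    @property
    def n_pairs(self) -> int:
        return n_unordered_pairs(len(self.ids))


@dataclass
class CloneAssignment:
    """Partition of patches into genets plus one representative per genet."""

    groups: dict[int, list[str]]
    representatives: dict[int, str]
    seed: int

    def __post_init__(self) -> None:
        members = [m for g in self.groups.values() for m in g]
        if len(members) != len(set(members)):
            raise ValueError("groups do not partition the patches")
        for gid, rep in self.representatives.items():
            if rep not in self.groups[gid]:
                raise ValueError(f"representative {rep!r} not in group {gid}")

    @property
    def representative_ids(self) -> list[str]:
        return [self.representatives[g] for g in sorted(self.groups)]

    def group_of(self) -> dict[str, int]:
        return {m: gid for gid, members in self.groups.items() for m in members}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "group": gid,
                "n_members": len(members),
                "representative": self.representatives[gid],
                "members": ";".join(members),
            }
            for gid, members in sorted(self.groups.items())
        ]
        return pd.DataFrame(rows)


def _allele_set_similarity(
    g: GenotypeTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Summed per-locus allele-set similarities and usable-locus counts.

    Returns ``(sim_sum, n_usable)`` as (n, n) arrays; the per-pair Lynch
    distance is ``1 - sim_sum / n_usable``.
    """
    n = g.n_individuals
    sim_sum = np.zeros((n, n))
    n_usable = np.zeros((n, n), dtype=np.int64)
    for j in range(g.n_loci):
        col = g.calls[:, j, :]
        typed = (col != MISSING).all(axis=1)
        alleles = np.unique(col[col != MISSING])
        if alleles.size == 0:
            continue
        # membership matrix Z: n x n_alleles, Z@Z.T = |A . B|
        z = (col[:, :, None] == alleles[None, None, :]).any(axis=1)
        z = z & typed[:, None]
        zf = z.astype(np.float64)
        inter = zf @ zf.T
        sizes = zf.sum(axis=1)
        denom = sizes[:, None] + sizes[None, :]
        pair_ok = typed[:, None] & typed[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(pair_ok, 2.0 * inter / denom, 0.0)
        sim_sum += np.nan_to_num(s)
        n_usable += pair_ok
    return sim_sum, n_usable


def lynch_distance_matrix(g: GenotypeTable) -> DistanceMatrix:
    """All pairwise Lynch distances for a genotype table.

    Pairs with no locus typed in both members get distance ``nan``.
    """
    sim_sum, n_usable = _allele_set_similarity(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - sim_sum / n_usable
    d[n_usable == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    # clip tiny negative round-off
    d = np.clip(d, 0.0, 1.0, out=d, where=np.isfinite(d))
    return DistanceMatrix(list(g.ids), d, n_usable)


def lynch_distance(g: GenotypeTable, id1: str, id2: str) -> float:
    """Lynch band-sharing distance between two individuals of a table."""
    sub = g.subset([i for i in g.ids if i in (id1, id2)])
    if id1 == id2:
        return 0.0
    dm = lynch_distance_matrix(sub)
    i, j = sub.ids.index(id1), sub.ids.index(id2)
    d = dm.values[i, j]
    if not np.isfinite(d):
        raise ValueError(f"{id1!r} and {id2!r} share no non-missing locus")
    return float(d)


def assign_clones(
    d: DistanceMatrix, threshold: float = 0.05, seed: int = 0
) -> CloneAssignment:
    """Group patches whose Lynch distance falls below ``threshold``.

    Grouping is single linkage (transitive closure of ``d < threshold``,
    strict inequality).  One representative per group is drawn uniformly
    at random with ``seed``; the seed is recorded in the output.
    Pairs with undefined distance (no shared typed locus) never merge.
    """
    v = d.values
    adj = np.isfinite(v) & (v < threshold)
    np.fill_diagonal(adj, False)
    n_groups, labels = connected_components(csr_matrix(adj), directed=False)
    rng = np.random.default_rng(seed)
    groups: dict[int, list[str]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(d.ids[idx])
    representatives = {
        gid: members[int(rng.integers(len(members)))]
        for gid, members in sorted(groups.items())
    }
    return CloneAssignment(groups, representatives, seed)


def probability_of_identity(
    f: AlleleFrequencyTable, loci_subset: list[str] | None = None
) -> float:
    """Multilocus probability of identity for a set of loci.

    Per locus ``PI_l = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2``; loci
    multiply (independent loci assumption).
    """
    loci = f.locus_names if loci_subset is None else list(loci_subset)
    if not loci:
        raise ValueError("empty locus subset")
    pi = 1.0
    for name in loci:
        _, p = f.arrays(name)
        a2 = float((p**2).sum())
        a4 = float((p**4).sum())
        # sum_{i<j} (2 p_i p_j)^2 = 2 * (a2^2 - a4)
        pi *= a4 + 2.0 * (a2**2 - a4)
    return pi


def pi_profile(f: AlleleFrequencyTable, max_combinations: int = 200) -> pd.DataFrame:
    """PI across marker-combination sizes (min/mean/max per panel size).

    For each subset size ``k`` of the locus panel, PI is evaluated for
    all (or up to ``max_combinations``) k-locus combinations.
    """
    loci = f.locus_names
    rows = []
    for k in range(1, len(loci) + 1):
        combos = list(itertools.combinations(loci, k))[:max_combinations]
        vals = [probability_of_identity(f, list(c)) for c in combos]
        rows.append(
            {
                "n_loci": k,
                "n_combinations": len(vals),
                "pi_min": min(vals),
                "pi_mean": float(np.mean(vals)),
                "pi_max": max(vals),
            }
        )
    return pd.DataFrame(rows)
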
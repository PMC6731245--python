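"""Candidate de novo mutation filters.

Two filter stacks are implemented over the long-format call table:

* offspring DNM candidates — region masks, reciprocal-cross VAF screens,
  a Poisson depth ceiling, either a parental alt-fraction screen
  ("reciprocal" mode) or a site-specific error screen from unrelated
  pedigrees ("error-rate" mode), and a minimum candidate VAF;
* parental very-early-embryonic (VEE) candidates — a stricter stack with
  Poisson sequencing-error and binomial constitutive-heterozygote tests.

Every removed candidate is recorded in a removal ledger with a single
named reason (the first failing filter in a fixed order); the retained set
itself is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

__all__ = [
    "FilterParams",
    "ParentalVEEParams",
    "RegionMask",
    "depth_cutoff",
    "mutation_specific_error",
    "filter_offspring_candidates",
    "filter_parental_vee_candidates",
]


@dataclass
class ParentalVEEParams:
    alt_in_other_parents_max: int = 1
    min_alt_reads: int = 5
    vaf_max: float = 0.35
    error_poisson_p_max: float = 0.02
    constitutive_binom_p_min: float = 0.003
    unrelated_vaf_max: float = 0.05


@dataclass
class FilterParams:
    reciprocal_offspring_vaf_max: float = 0.20
    reciprocal_parent_vaf_max: float = 0.04
    depth_quantile: float = 1e-4
    parent_alt_fraction_max: float = 0.05
    mutation_specific_error_max: float = 0.02
    candidate_vaf_min: float = 0.15
    parental_vee: ParentalVEEParams = field(default_factory=ParentalVEEParams)

    def __post_init__(self) -> None:
        for name in (
            "reciprocal_offspring_vaf_max",
            "reciprocal_parent_vaf_max",
            "parent_alt_fraction_max",
            "mutation_specific_error_max",
            "candidate_vaf_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.depth_quantile < 1.0:
            raise ValueError("depth_quantile must lie in (0, 1)")


class RegionMask:
    """Point-in-interval lookup over BED intervals (repeats, segdups).

    BED is half-open 0-based; a 1-based position p is masked when
    start < p <= end for some interval on its chromosome.
    """

    def __init__(self, intervals: dict[str, np.ndarray]):
        # per chrom: (n, 2) array of merged, sorted [start, end) pairs
        self._intervals = intervals

    @classmethod
    def from_bed(cls, path: str) -> "RegionMask":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            comment="#",
        )
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionMask":
        out: dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom"):
            iv = grp[["start", "end"]].to_numpy(dtype=np.int64)
            iv = iv[np.argsort(iv[:, 0])]
            merged = []
            for s, e in iv:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[str(chrom)] = np.asarray(merged, dtype=np.int64)
        return cls(out)

    @classmethod
    def empty(cls) -> "RegionMask":
        return cls({})

    def contains(self, chrom: str, pos: int) -> bool:
        iv = self._intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return False
        i = int(np.searchsorted(iv[:, 0], pos - 1, side="right")) - 1
        return i >= 0 and pos - 1 < iv[i, 1]


def depth_cutoff(mean_depth: float, quantile: float = 1e-4) -> int:
    """Smallest depth d with upper-tail probability P(D > d) < quantile for
    D ~ Poisson(mean_depth); sites deeper than d are removed."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    d = int(stats.poisson.isf(quantile, mean_depth))
    # isf can overshoot by one on ties; walk to the exact boundary
    while d > 0 and stats.poisson.sf(d - 1, mean_depth) < quantile:
        d -= 1
    while stats.poisson.sf(d, mean_depth) >= quantile:
        d += 1
    return d


def mutation_specific_error(
    unrelated_counts: list[tuple[int, int]]
) -> Optional[float]:
    """Pooled alt fraction across unrelated individuals at a candidate site.

    ``unrelated_counts`` holds ``(alt, depth)`` pairs.  Returns ``None``
    (site unfilterable) when the pooled depth is zero.
    """
    alt = sum(a for a, _ in unrelated_counts)
    depth = sum(d for _, d in unrelated_counts)
    if depth == 0:
        return None
    return alt / depth


def _pooled(calls: pd.DataFrame) -> pd.DataFrame:
    """Pool tissue rows to one row per (site, individual)."""
    g = calls.groupby(
        ["chrom", "pos", "ref", "alt", "individual"], as_index=False, sort=False
    )[["ref_reads", "alt_reads"]].sum()
    g["depth"] = g["ref_reads"] + g["alt_reads"]
    g["vaf"] = np.where(g["depth"] > 0, g["alt_reads"] / g["depth"].replace(0, 1), np.nan)
    return g


_SITE_KEY = ["chrom", "pos", "ref", "alt"]


def filter_offspring_candidates(
    calls: pd.DataFrame,
    pedigree: Pedigree,
    params: Optional[FilterParams] = None,
    mask: Optional[RegionMask] = None,
    mode: str = "error-rate",
    site_errors: Optional[dict[tuple, float]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter offspring DNM candidates from a long-format call table.

    ``calls`` has columns chrom, pos, ref, alt, individual, tissue,
    ref_reads, alt_reads and carries counts for every sequenced individual
    at every candidate site.  A candidate is any (site, offspring) pair
    with at least one alt read.  Returns ``(retained, ledger)`` where
    ``retained`` is one pooled row per surviving candidate and ``ledger``
    names the first failing filter per removed candidate.

    ``mode`` selects the parental screen: ``"reciprocal"`` removes sites
    with parental alt fraction above ``parent_alt_fraction_max`` plus the
    reciprocal-pedigree VAF screens; ``"error-rate"`` instead removes sites
    whose pooled alt fraction in unrelated pedigrees exceeds
    ``mutation_specific_error_max``.
    """
    if mode not in ("reciprocal", "error-rate"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or FilterParams()
    mask = mask or RegionMask.empty()

    for ind in calls["individual"].unique():
        if ind not in pedigree:
            raise ValueError(f"call table references unknown individual {ind!r}")

    pooled = _pooled(calls)
    roles = {i: pedigree[i].role for i in pooled["individual"].unique()}
    pooled["role"] = pooled["individual"].map(roles)

    # mean depth per individual, for the Poisson depth ceiling
    mean_depth = pooled.groupby("individual")["depth"].mean().to_dict()
    cutoffs = {i: depth_cutoff(md, params.depth_quantile) for i, md in mean_depth.items() if md > 0}

    # per-site parental and unrelated aggregates
    parents_by_site: dict[tuple, dict[str, tuple[int, int]]] = {}
    unrelated_by_site: dict[tuple, dict[str, list[tuple[int, int]]]] = {}
    for row in pooled.itertuples(index=False):
        key = (row.chrom, row.pos, row.ref, row.alt)
        if row.role == "parent":
            parents_by_site.setdefault(key, {})[row.individual] = (
                row.alt_reads,
                row.depth,
            )
        ped_id = pedigree[row.individual].pedigree_id
        unrelated_by_site.setdefault(key, {}).setdefault(ped_id, []).append(
            (row.alt_reads, row.depth)
        )

    candidates = pooled[(pooled["role"] == "offspring") & (pooled["alt_reads"] > 0)]

    retained_rows, ledger_rows = [], []
    for row in candidates.itertuples(index=False):
        key = (row.chrom, row.pos, row.ref, row.alt)
        ind = row.individual
        fam = pedigree[ind].pedigree_id
        reason = None

        if mask.contains(row.chrom, row.pos):
            reason = "region_mask"

        if reason is None and mode == "reciprocal":
            # screen against offspring/parents of every *other* pedigree
            other = [
                r
                for r in pooled[
                    (pooled.chrom == row.chrom)
                    & (pooled.pos == row.pos)
                    & (pooled.ref == row.ref)
                    & (pooled.alt == row.alt)
                ].itertuples(index=False)
                if pedigree[r.individual].pedigree_id != fam and r.depth > 0
            ]
            for r in other:
                vaf = r.alt_reads / r.depth
                limit = (
                    params.reciprocal_parent_vaf_max
                    if pedigree[r.individual].role == "parent"
                    else params.reciprocal_offspring_vaf_max
                )
                if vaf > limit:
                    reason = "reciprocal_cross"
                    break

        if reason is None:
            cut = cutoffs.get(ind)
            if cut is not None and row.depth > cut:
                reason = "depth_ceiling"

        if reason is None:
            if mode == "reciprocal":
                mother = pedigree.mother_of(ind).id
                father = pedigree.father_of(ind).id
                for pid in (mother, father):
                    a, d = parents_by_site.get(key, {}).get(pid, (0, 0))
                    if d > 0 and a / d > params.parent_alt_fraction_max:
                        reason = "parental_support"
                        break
            else:
                err = None
                if site_errors is not None:
                    err = site_errors.get(key)
                if err is None:
                    unrelated = [
                        c
                        for other_fam, counts in unrelated_by_site.get(key, {}).items()
                        if other_fam != fam
                        for c in counts
                    ]
                    err = mutation_specific_error(unrelated) if unrelated else None
                if err is not None and err > params.mutation_specific_error_max:
                    reason = "mutation_specific_error"

        if reason is None and row.depth > 0 and row.vaf < params.candidate_vaf_min:
            reason = "low_vaf"

        if reason is None:
            retained_rows.append(row)
        else:
            ledger_rows.append(
                {
                    "chrom": row.chrom,
                    "pos": row.pos,
                    "ref": row.ref,
                    "alt": row.alt,
                    "individual": ind,
                    "reason": reason,
                }
            )

    retained = pd.DataFrame(retained_rows, columns=list(candidates.columns))
    ledger = pd.DataFrame(
        ledger_rows, columns=_SITE_KEY + ["individual", "reason"]
    )
    return retained, ledger


def filter_parental_vee_candidates(
    calls: pd.DataFrame,
    pedigree: Pedigree,
    params: Optional[FilterParams] = None,
    mask: Optional[RegionMask] = None,
    strain_variants: Optional[set[tuple]] = None,
) -> pd.DataFrame:
    """Filter candidate VEE mutations in parents (mosaic in parental soma).

    A candidate is a (site, parent) pair with at least one alt read.  The
    stack, in order: strain-variant exclusion, region masks, single-parent
    constraint within the pedigree, unrelated-individual VAF screen,
    Poisson sequencing-error probability, binomial constitutive-het
    probability, alt-read screen in other parents, minimum alt reads and
    maximum VAF in the candidate.  Returns the retained pooled rows with
    the computed probabilities attached.
    """
    params = params or FilterParams()
    vee = params.parental_vee
    mask = mask or RegionMask.empty()
    strain_variants = strain_variants or set()

    pooled = _pooled(calls)
    pooled["role"] = pooled["individual"].map(lambda i: pedigree[i].role)
    parents = pooled[pooled["role"] == "parent"]

    retained = []
    for row in parents[parents["alt_reads"] > 0].itertuples(index=False):
        key = (row.chrom, row.pos, row.ref, row.alt)
        ind = row.individual
        fam = pedigree[ind].pedigree_id
        if key in strain_variants:
            continue
        if mask.contains(row.chrom, row.pos):
            continue

        site_rows = pooled[
            (pooled.chrom == row.chrom)
            & (pooled.pos == row.pos)
            & (pooled.ref == row.ref)
            & (pooled.alt == row.alt)
        ]
        unrelated_rows = site_rows[
            [pedigree[i].pedigree_id != fam for i in site_rows.individual]
        ]
        unrelated_ok = True
        for r in unrelated_rows.itertuples(index=False):
            if r.depth > 0 and r.alt_reads / r.depth >= vee.unrelated_vaf_max:
                unrelated_ok = False
                break
        if not unrelated_ok:
            continue

        err = mutation_specific_error(
            [(r.alt_reads, r.depth) for r in unrelated_rows.itertuples(index=False)]
        )
        if err is None:
            continue  # unfilterable site
        # probability of the observed alt count under sequencing error alone:
        # upper tail of Poisson(depth x error rate)
        p_err = float(stats.poisson.sf(row.alt_reads - 1, row.depth * err))
        if p_err > vee.error_poisson_p_max:
            continue
        # probability the site is a constitutive het: lower tail of
        # Binomial(depth, 0.5) at the observed alt count
        p_const = float(stats.binom.cdf(row.alt_reads, row.depth, 0.5))
        if p_const > vee.constitutive_binom_p_min:
            continue

        all_other_parents = site_rows[
            (site_rows.role == "parent") & (site_rows.individual != ind)
        ]
        if (all_other_parents.alt_reads > vee.alt_in_other_parents_max).any():
            continue
        if row.alt_reads < vee.min_alt_reads:
            continue
        if row.depth > 0 and row.vaf > vee.vaf_max:
            continue
        rec = row._asdict()
        rec["error_rate"] = err
        rec["p_error"] = p_err
        rec["p_constitutive"] = p_const
        retained.append(rec)

    cols = list(parents.columns) + ["error_rate", "p_error", "p_constitutive"]
    return pd.DataFrame(retained, columns=cols)
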
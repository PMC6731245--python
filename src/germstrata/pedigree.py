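"""Core domain types: pedigrees, individuals, tissue observations, mutation
calls/events and the multi-nucleotide variant (MNV) merging rule.

A :class:`MutationCall` is one candidate de novo mutation observed in one
individual, with per-tissue read counts and optional read-pair phase
evidence.  Calls at nearby positions in the same individual are merged into
a single :class:`MutationEvent` (``merge_mnv``), the unit that all
downstream classification and rate estimation operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "SEXES",
    "ROLES",
    "TIERS",
    "Individual",
    "TissueObservation",
    "PhaseEvidence",
    "MutationCall",
    "MutationEvent",
    "Pedigree",
    "is_autosome",
    "merge_mnv",
]

SEXES = ("male", "female")
ROLES = ("parent", "offspring")
TIERS = ("wgs", "genotyped_only")

_BASES = frozenset("ACGT")
_SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


def is_autosome(chrom: str) -> bool:
    """True unless ``chrom`` names a sex chromosome (X/Y, with or without a
    ``chr`` prefix)."""
    return chrom not in _SEX_CHROMS


@dataclass
class Individual:
    """One sequenced or genotyped animal/person in a pedigree."""

    id: str
    sex: str
    role: str
    pedigree_id: str
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    litter_index: Optional[int] = None
    parental_age_weeks: Optional[float] = None
    sequencing_tier: str = "wgs"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.sequencing_tier not in TIERS:
            raise ValueError(f"unknown sequencing tier {self.sequencing_tier!r}")
        if self.role == "offspring":
            if self.mother_id is None or self.father_id is None:
                raise ValueError(f"offspring {self.id} must reference both parents")
            if self.litter_index is not None and self.litter_index < 0:
                raise ValueError("litter_index must be non-negative")
            if self.parental_age_weeks is not None and self.parental_age_weeks <= 0:
                raise ValueError("parental_age_weeks must be positive")


@dataclass(frozen=True)
class TissueObservation:
    """Allele counts for one mutation site in one tissue of one individual."""

    tissue: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def vaf(self) -> Optional[float]:
        """Variant allele fraction; ``None`` when depth is zero."""
        d = self.depth
        return self.alt_reads / d if d > 0 else None


@dataclass(frozen=True)
class PhaseEvidence:
    """Read-pair phasing of a mutation onto a parental haplotype.

    ``informative_pairs_total`` counts read pairs spanning both the mutation
    and an informative heterozygous site on the haplotype of origin;
    ``informative_pairs_with_alt`` is how many of those carry the derived
    allele.  Their ratio is the haplotype occupancy (HO).
    """

    origin: str = "unknown"  # paternal | maternal | unknown
    informative_pairs_total: int = 0
    informative_pairs_with_alt: int = 0

    def __post_init__(self) -> None:
        if self.origin not in ("paternal", "maternal", "unknown"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.informative_pairs_with_alt > self.informative_pairs_total:
            raise ValueError("alt-carrying pairs exceed total informative pairs")
        if min(self.informative_pairs_total, self.informative_pairs_with_alt) < 0:
            raise ValueError("pair counts must be non-negative")


@dataclass
class MutationCall:
    """A candidate de novo SNV observed in one individual.

    Only biallelic autosomal SNVs are representable: sex chromosomes and
    indels are rejected at construction (ingest-time exclusions).
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    individual_id: str
    observations: list[TissueObservation]
    phase: Optional[PhaseEvidence] = None
    context_5prime: Optional[str] = None
    context_3prime: Optional[str] = None

    def __post_init__(self) -> None:
        if not is_autosome(self.chrom):
            raise ValueError(f"non-autosomal chrom {self.chrom!r} rejected")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError("ref/alt must be single bases A, C, G or T (no indels)")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not self.observations:
            raise ValueError("at least one TissueObservation is required")
        for ctx in (self.context_5prime, self.context_3prime):
            if ctx is not None and ctx not in _BASES:
                raise ValueError(f"context base {ctx!r} must be A/C/G/T or None")

    @property
    def alt_total(self) -> int:
        return sum(o.alt_reads for o in self.observations)

    @property
    def depth_total(self) -> int:
        return sum(o.depth for o in self.observations)

    @property
    def pooled_vaf(self) -> Optional[float]:
        d = self.depth_total
        return self.alt_total / d if d > 0 else None

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class MutationEvent:
    """A unique mutational event: one or more merged call sites in one
    individual, plus the cross-individual annotations attached downstream."""

    member_calls: list[MutationCall]
    carrier_offspring: set[str] = field(default_factory=set)
    stratum: Optional[object] = None  # strata_classifier.StratumCall once assigned
    parental_origin: str = "unknown"
    germline_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.member_calls:
            raise ValueError("an event needs at least one member call")
        chroms = {c.chrom for c in self.member_calls}
        if len(chroms) != 1:
            raise ValueError("member calls must share one chromosome")
        if not 0.0 <= self.germline_weight <= 1.0:
            raise ValueError("germline_weight must lie in [0, 1]")

    @property
    def chrom(self) -> str:
        return self.member_calls[0].chrom

    @property
    def pos(self) -> int:
        return min(c.pos for c in self.member_calls)

    @property
    def individual_id(self) -> str:
        return self.member_calls[0].individual_id

    @property
    def event_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def n_sites(self) -> int:
        return len(self.member_calls)

    @property
    def is_mnv(self) -> bool:
        return self.n_sites > 1


class Pedigree:
    """A set of related individuals (possibly spanning several independent
    two-parent pedigrees) with parent/offspring lookups."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise ValueError(f"duplicate individual id {ind.id}")
            self.individuals[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self.individuals.values():
            if ind.role != "offspring":
                continue
            for pid, want_sex in ((ind.mother_id, "female"), (ind.father_id, "male")):
                parent = self.individuals.get(pid)
                if parent is None:
                    raise ValueError(f"offspring {ind.id} references missing parent {pid}")
                if parent.pedigree_id != ind.pedigree_id:
                    raise ValueError(f"offspring {ind.id} and parent {pid} are in different pedigrees")
                if parent.sex != want_sex:
                    raise ValueError(f"parent {pid} of {ind.id} has unexpected sex")

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.individuals

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[individual_id]

    def __len__(self) -> int:
        return len(self.individuals)

    def mother_of(self, individual_id: str) -> Individual:
        return self.individuals[self.individuals[individual_id].mother_id]

    def father_of(self, individual_id: str) -> Individual:
        return self.individuals[self.individuals[individual_id].father_id]

    def offspring(self, pedigree_id: Optional[str] = None) -> list[Individual]:
        return [
            i
            for i in self.individuals.values()
            if i.role == "offspring" and (pedigree_id is None or i.pedigree_id == pedigree_id)
        ]

    def parents(self, pedigree_id: Optional[str] = None) -> list[Individual]:
        return [
            i
            for i in self.individuals.values()
            if i.role == "parent" and (pedigree_id is None or i.pedigree_id == pedigree_id)
        ]

    def pedigree_ids(self) -> list[str]:
        return sorted({i.pedigree_id for i in self.individuals.values()})

    def unrelated_to(self, individual_id: str) -> list[Individual]:
        """Members of every other pedigree (used for site-error estimation)."""
        fam = self.individuals[individual_id].pedigree_id
        return [i for i in self.individuals.values() if i.pedigree_id != fam]


def merge_mnv(calls: list[MutationCall], max_gap: int = 5) -> list[MutationEvent]:
    """Merge clustered call sites of one individual into events.

    Sites on the same chromosome within ``max_gap`` bp of any member of a
    growing cluster join that cluster (transitive chaining); each cluster
    becomes a single :class:`MutationEvent` counted as one mutation.
    Coordinates are 1-based and distance is ``|pos_a - pos_b|``.
    """
    if not calls:
        return []
    individuals = {c.individual_id for c in calls}
    if len(individuals) != 1:
        raise ValueError("merge_mnv operates on calls from a single individual")
    events: list[MutationEvent] = []
    by_chrom: dict[str, list[MutationCall]] = {}
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom_calls in by_chrom.values():
        cluster = [chrom_calls[0]]
        for c in chrom_calls[1:]:
            if c.pos - cluster[-1].pos <= max_gap:
                cluster.append(c)
            else:
                events.append(MutationEvent(member_calls=cluster))
                cluster = [c]
        events.append(MutationEvent(member_calls=cluster))
    events.sort(key=lambda e: (e.chrom, e.pos))
    return events
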
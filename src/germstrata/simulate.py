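"""Pedigree and germline-mutation simulator.

Generates two-parent pedigrees with timed litters, draws mutations along an
explicit germline genealogy — offspring first cleavage (VEE), parental
embryonic divisions before PGC specification (EE), around PGC specification
(peri-PGC) and the post-PGC / spermatogonial stem cell phase (late
post-PGC) — and renders the resulting cell fractions as read counts at
configurable sequencing depths with a per-base error rate.

Generative model, per stage (rates are haploid, per base per cell division;
``G`` is the genome size):

* VEE: each offspring zygote's first cleavage contributes
  ``Poisson(2 r G)`` mutations at cell fraction 0.5 (expected read VAF
  0.25), absent from the parents.
* EE: each parent's germline founder lineage accumulates
  ``Poisson(2 r d G)`` mutations over ``d`` embryonic divisions; each is
  mosaic in parental soma (cell fraction drawn in (0.016, 0.20]) and is
  transmitted to each offspring independently with probability 1/2
  (the homolog coin flip), arriving constitutive.
* peri-PGC: each parent draws ``Poisson(2 r d G)`` mutations assigned
  uniformly to one of ``n_pgc_founders`` founder lineages; every offspring
  descends (per parent) from one founder lineage drawn from a Dirichlet
  weight vector, and carries exactly the mutations of that lineage.
  Parental soma is clean.
* late post-PGC: each transmitted gamete carries
  ``Poisson(r d G)`` mutations from its sex's post-PGC divisions, plus —
  paternally — ``Poisson(r_ssc G n_extra)`` where ``n_extra`` counts SSC
  divisions accrued past puberty at the father's age at conception.

``expected_haploid_rate_per_generation`` returns the closed-form expected
per-generation haploid rate implied by a configuration (VEE weighted by its
expected germline contribution), which downstream estimators should
recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_pedigree",
    "simulate_germline",
    "simulate_reads",
    "expected_mutations_per_offspring",
    "expected_haploid_rate_per_generation",
]

_BASES = np.array(list("ACGT"))

WEEKS_PER_YEAR = 52.1775


@dataclass
class SimulationConfig:
    seed: int = 0
    n_pedigrees: int = 1
    n_offspring_wgs: int = 10
    n_offspring_genotyped: int = 10
    n_litters: int = 5
    litter_gap_weeks: float = 8.0
    age_first_litter_weeks: float = 16.0
    puberty_weeks: float = 52.1775 / 12.0  # one month
    ssc_divisions_per_year: float = 42.0

    # haploid mutation rates per base per cell division
    rate_first_cleavage: float = 1.1e-9
    rate_embryonic: float = 5e-11
    rate_peri_pgc: float = 4e-10
    rate_post_pgc: float = 1.0e-10
    rate_ssc_per_division: float = 5e-11

    # divisions per stage (per sex where they differ)
    divisions_embryonic: int = 10
    divisions_peri_pgc: int = 2
    divisions_post_pgc_paternal: int = 24
    divisions_post_pgc_maternal: int = 13
    n_pgc_founders: int = 8

    genome_size: int = 2_222_635_788

    wgs_depth_mean: float = 25.0
    targeted_parent_depth_mean: float = 600.0
    targeted_offspring_depth_mean: float = 400.0
    genotyped_offspring_depth_mean: float = 200.0
    error_rate: float = 1e-4

    # linear transmission model used when weighting VEE germline contributions
    vee_beta0: float = 0.0
    vee_beta1: float = 1.0
    # optional Gamma(shape, scale=1/shape) per-zygote multiplier on the VEE
    # rate, reproducing over-dispersion of VEE counts; None disables it
    vee_overdispersion_shape: Optional[float] = None
    # when True, VEE mutations may also arise in divisions 2-3 at halving
    # cell fractions (power studies); default restricts to the first division
    vee_later_divisions: bool = False

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name.startswith("rate_") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        for name in (
            "wgs_depth_mean",
            "targeted_parent_depth_mean",
            "targeted_offspring_depth_mean",
            "genotyped_offspring_depth_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_offspring_wgs + self.n_offspring_genotyped < 1:
            raise ValueError("at least one offspring is required")
        if self.n_pgc_founders < 1:
            raise ValueError("n_pgc_founders must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth for one simulated mutation event."""

    event_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    pedigree_id: str
    true_stratum: str  # VEE | EE | peri_PGC | late_post_PGC
    parental_origin: str  # paternal | maternal | unknown
    cell_fraction: dict[str, float] = field(default_factory=dict)
    carrier_offspring: set[str] = field(default_factory=set)
    context_5prime: str = "A"
    context_3prime: str = "A"
    lineage: Optional[int] = None  # peri-PGC founder lineage index


def _father_age_weeks(cfg: SimulationConfig, litter: int) -> float:
    return cfg.age_first_litter_weeks + litter * cfg.litter_gap_weeks


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Build the pedigree skeleton: two parents per pedigree plus WGS and
    genotyped-only offspring spread round-robin across litters."""
    individuals: list[Individual] = []
    for p in range(cfg.n_pedigrees):
        ped = f"PED{p}"
        father, mother = f"{ped}_F", f"{ped}_M"
        individuals.append(Individual(father, "male", "parent", ped))
        individuals.append(Individual(mother, "female", "parent", ped))
        n_total = cfg.n_offspring_wgs + cfg.n_offspring_genotyped
        for k in range(n_total):
            litter = k % cfg.n_litters
            tier = "wgs" if k < cfg.n_offspring_wgs else "genotyped_only"
            individuals.append(
                Individual(
                    id=f"{ped}_O{k}",
                    sex="male" if k % 2 == 0 else "female",
                    role="offspring",
                    pedigree_id=ped,
                    mother_id=mother,
                    father_id=father,
                    litter_index=litter,
                    parental_age_weeks=_father_age_weeks(cfg, litter),
                    sequencing_tier=tier,
                )
            )
    return Pedigree(individuals)


def _draw_sites(rng: np.random.Generator, n: int, cfg: SimulationConfig, used: set[int]):
    """Random distinct autosomal sites with ref/alt alleles and context."""
    out = []
    while len(out) < n:
        pos = int(rng.integers(2, cfg.genome_size - 1))
        if pos in used:
            continue
        used.add(pos)
        ref, alt = rng.choice(4, size=2, replace=False)
        c5, c3 = rng.integers(0, 4, size=2)
        out.append((pos, _BASES[ref], _BASES[alt], _BASES[c5], _BASES[c3]))
    return out


def simulate_germline(cfg: SimulationConfig) -> tuple[Pedigree, list[TruthRecord]]:
    """Simulate mutation truth along the germline genealogy.

    Returns the pedigree and one :class:`TruthRecord` per mutation that is
    carried by at least one offspring (events invisible to a pedigree
    screen — e.g. untransmitted parental mutations — are not emitted).
    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg)
    G = cfg.genome_size
    records: list[TruthRecord] = []
    used_pos: set[int] = set()
    counter = 0

    def new_records(n, ped_id, stratum, origin, lineage=None):
        nonlocal counter
        recs = []
        for pos, ref, alt, c5, c3 in _draw_sites(rng, n, cfg, used_pos):
            recs.append(
                TruthRecord(
                    event_id=f"mut{counter}",
                    chrom="chr1",
                    pos=pos,
                    ref=str(ref),
                    alt=str(alt),
                    pedigree_id=ped_id,
                    true_stratum=stratum,
                    parental_origin=origin,
                    context_5prime=str(c5),
                    context_3prime=str(c3),
                    lineage=lineage,
                )
            )
            counter += 1
        return recs

    for ped_id in ped.pedigree_ids():
        offspring = sorted(ped.offspring(ped_id), key=lambda i: i.id)
        father = next(i for i in ped.parents(ped_id) if i.sex == "male")
        mother = next(i for i in ped.parents(ped_id) if i.sex == "female")

        # --- VEE: offspring first cleavage ------------------------------
        for child in offspring:
            lam = 2.0 * cfg.rate_first_cleavage * G
            if cfg.vee_overdispersion_shape is not None:
                shape = cfg.vee_overdispersion_shape
                lam *= rng.gamma(shape, 1.0 / shape)
            n = rng.poisson(lam)
            for rec in new_records(n, ped_id, "VEE", "unknown"):
                frac = 0.5
                if cfg.vee_later_divisions and rng.random() < 0.25:
                    frac = 0.25  # second-division event
                rec.cell_fraction[child.id] = frac
                rec.carrier_offspring = {child.id}
                records.append(rec)

        # --- EE: parental embryonic divisions ---------------------------
        for parent, origin in ((father, "paternal"), (mother, "maternal")):
            n = rng.poisson(2.0 * cfg.rate_embryonic * cfg.divisions_embryonic * G)
            for rec in new_records(n, ped_id, "EE", origin):
                soma = float(rng.uniform(0.016, 0.20))
                rec.cell_fraction[parent.id] = soma
                carriers = {c.id for c in offspring if rng.random() < 0.5}
                if not carriers:
                    continue  # never transmitted: invisible to the screen
                rec.carrier_offspring = carriers
                for cid in carriers:
                    rec.cell_fraction[cid] = 1.0
                records.append(rec)

        # --- peri-PGC: founder lineages ---------------------------------
        for parent, origin in ((father, "paternal"), (mother, "maternal")):
            weights = rng.dirichlet(np.ones(cfg.n_pgc_founders))
            child_lineage = {
                c.id: int(rng.choice(cfg.n_pgc_founders, p=weights)) for c in offspring
            }
            n = rng.poisson(2.0 * cfg.rate_peri_pgc * cfg.divisions_peri_pgc * G)
            for rec in new_records(n, ped_id, "peri_PGC", origin):
                lin = int(rng.integers(cfg.n_pgc_founders))
                carriers = {cid for cid, l in child_lineage.items() if l == lin}
                if not carriers:
                    continue
                rec.lineage = lin
                rec.carrier_offspring = carriers
                for cid in carriers:
                    rec.cell_fraction[cid] = 1.0
                # a single-carrier peri-PGC draw is observationally a late
                # post-PGC mutation; label by what a perfect observer sees
                if len(carriers) < 2:
                    rec.true_stratum = "late_post_PGC"
                records.append(rec)

        # --- late post-PGC: per-gamete ----------------------------------
        for child in offspring:
            extra_years = max(
                0.0, (child.parental_age_weeks - cfg.puberty_weeks) / WEEKS_PER_YEAR
            )
            lam_pat = (
                cfg.rate_post_pgc * cfg.divisions_post_pgc_paternal
                + cfg.rate_ssc_per_division * cfg.ssc_divisions_per_year * extra_years
            ) * G
            lam_mat = cfg.rate_post_pgc * cfg.divisions_post_pgc_maternal * G
            for origin, lam in (("paternal", lam_pat), ("maternal", lam_mat)):
                n = rng.poisson(lam)
                for rec in new_records(n, ped_id, "late_post_PGC", origin):
                    rec.carrier_offspring = {child.id}
                    rec.cell_fraction[child.id] = 1.0
                    records.append(rec)

    return ped, records


_PARENT_TISSUES = ("spleen", "kidney", "tail")
_WGS_TISSUES = ("spleen", "kidney")
_GENOTYPED_TISSUES = ("tail",)


def simulate_reads(
    pedigree: Pedigree,
    truth: list[TruthRecord],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Render truth records as a long-format call table.

    For every truth site and every individual in the same pedigree, each of
    the individual's assay tissues receives ``depth ~ Poisson(mean)`` reads
    with ``alt ~ Binomial(depth, cell_fraction / 2)`` for carriers and
    ``alt ~ Binomial(depth, error_rate)`` for non-carriers.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)

    chroms, poss, refs, alts, inds, tissues = [], [], [], [], [], []
    fracs, depth_means = [], []
    for rec in truth:
        for ind in pedigree.individuals.values():
            if ind.pedigree_id != rec.pedigree_id:
                continue
            if ind.role == "parent":
                tset, dmean = _PARENT_TISSUES, cfg.targeted_parent_depth_mean
            elif ind.sequencing_tier == "wgs":
                tset, dmean = _WGS_TISSUES, cfg.targeted_offspring_depth_mean
            else:
                tset, dmean = _GENOTYPED_TISSUES, cfg.genotyped_offspring_depth_mean
            f = rec.cell_fraction.get(ind.id, 0.0)
            for t in tset:
                chroms.append(rec.chrom)
                poss.append(rec.pos)
                refs.append(rec.ref)
                alts.append(rec.alt)
                inds.append(ind.id)
                tissues.append(t)
                fracs.append(f)
                depth_means.append(dmean)

    depth = rng.poisson(np.asarray(depth_means))
    frac = np.asarray(fracs)
    p_alt = np.where(frac > 0, frac / 2.0, cfg.error_rate)
    alt_reads = rng.binomial(depth, p_alt)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": poss,
            "ref": refs,
            "alt": alts,
            "individual": inds,
            "tissue": tissues,
            "ref_reads": depth - alt_reads,
            "alt_reads": alt_reads,
        }
    )


def _mean_extra_ssc_years(cfg: SimulationConfig) -> float:
    ages = [
        _father_age_weeks(cfg, k % cfg.n_litters)
        for k in range(cfg.n_offspring_wgs + cfg.n_offspring_genotyped)
    ]
    return float(
        np.mean([max(0.0, (a - cfg.puberty_weeks) / WEEKS_PER_YEAR) for a in ages])
    )


def expected_mutations_per_offspring(cfg: SimulationConfig) -> dict[str, float]:
    """Closed-form expected diploid mutation counts per offspring by stage
    (VEE reported both raw and weighted by expected germline contribution)."""
    G = cfg.genome_size
    vee_raw = 2.0 * cfg.rate_first_cleavage * G
    ee = 2.0 * cfg.rate_embryonic * cfg.divisions_embryonic * G
    peri = 4.0 * cfg.rate_peri_pgc * cfg.divisions_peri_pgc * G / cfg.n_pgc_founders
    post = (
        cfg.rate_post_pgc
        * (cfg.divisions_post_pgc_paternal + cfg.divisions_post_pgc_maternal)
        * G
        + cfg.rate_ssc_per_division
        * cfg.ssc_divisions_per_year
        * _mean_extra_ssc_years(cfg)
        * G
    )
    # a VEE at cell fraction f reaches a fraction f/2 of gametes; the
    # adjusted (germline-weighted) diploid count is 2 * (b0 + b1 * f/2)
    vee_weighted = vee_raw * 2.0 * (cfg.vee_beta0 + cfg.vee_beta1 * 0.25)
    return {
        "VEE_raw": vee_raw,
        "VEE_weighted": vee_weighted,
        "EE": ee,
        "peri_PGC": peri,
        "late_post_PGC": post,
        "total_weighted": vee_weighted + ee + peri + post,
    }


def expected_haploid_rate_per_generation(cfg: SimulationConfig) -> float:
    """Expected per-generation haploid mutation rate per base implied by the
    configuration (germline-weighted diploid count / 2 / genome size)."""
    exp = expected_mutations_per_offspring(cfg)
    return exp["total_weighted"] / 2.0 / cfg.genome_size
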
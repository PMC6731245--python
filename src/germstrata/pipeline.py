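"""End-to-end driver: retained candidates -> events -> strata -> rates,
spectra and lineages, with a reproducible run manifest."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierParams, StratumCall, classify_event
from .filtering import FilterParams, RegionMask, filter_offspring_candidates, mutation_specific_error
from .lineage import LineagePartition, SharingMatrix, reconstruct_lineages
from .pedigree import MutationCall, MutationEvent, Pedigree, TissueObservation
from .rates import (
    GermlineDemography,
    RateSet,
    SensitivityCorrections,
    VEETransmissionModel,
    adjusted_vee_count,
    corrected_mean_mutations,
    rate_set,
)
from .spectra import SpectrumProfile, spectrum

__all__ = ["PipelineResult", "build_events", "classify_events", "estimate_rates", "run_pipeline"]

_SITE_KEY = ["chrom", "pos", "ref", "alt"]
_PARENT_TISSUE_COUNT = 3


def build_events(
    retained: pd.DataFrame,
    pedigree: Pedigree,
    max_gap: int = 5,
) -> list[MutationEvent]:
    """Group retained (site, offspring) candidates into unique events.

    Sites within ``max_gap`` bp on the same chromosome are one MNV event;
    an event's carriers are all offspring retained at any member site.
    """
    if retained.empty:
        return []
    sites = retained[_SITE_KEY].drop_duplicates().sort_values(["chrom", "pos"])
    clusters: list[list[tuple]] = []
    last_chrom, last_pos = None, None
    for row in sites.itertuples(index=False):
        if row.chrom == last_chrom and row.pos - last_pos <= max_gap:
            clusters[-1].append(tuple(row))
        else:
            clusters.append([tuple(row)])
        last_chrom, last_pos = row.chrom, row.pos
    events = []
    grouped = retained.groupby(_SITE_KEY)
    for cluster in clusters:
        calls, carriers = [], set()
        for key in cluster:
            rows = grouped.get_group(key)
            carriers |= set(rows["individual"])
            first = rows.iloc[0]
            calls.append(
                MutationCall(
                    chrom=first["chrom"],
                    pos=int(first["pos"]),
                    ref_allele=first["ref"],
                    alt_allele=first["alt"],
                    individual_id=first["individual"],
                    observations=[
                        TissueObservation(
                            "pooled", int(first["ref_reads"]), int(first["alt_reads"])
                        )
                    ],
                )
            )
        events.append(MutationEvent(member_calls=calls, carrier_offspring=carriers))
    return events


def classify_events(
    events: list[MutationEvent],
    calls: pd.DataFrame,
    pedigree: Pedigree,
    params: Optional[ClassifierParams] = None,
) -> pd.DataFrame:
    """Classify every event, returning the strata table."""
    params = params or ClassifierParams()
    pooled = calls.groupby(
        _SITE_KEY + ["individual"], as_index=False, sort=False
    )[["ref_reads", "alt_reads"]].sum()
    pooled_idx: dict[tuple, tuple[int, int]] = {}
    for r in pooled.itertuples(index=False):
        pooled_idx[(r.chrom, r.pos, r.ref, r.alt, r.individual)] = (
            r.alt_reads,
            r.alt_reads + r.ref_reads,
        )
    tissue_idx: dict[tuple, list[tuple[int, int]]] = {}
    for r in calls.itertuples(index=False):
        tissue_idx.setdefault((r.chrom, r.pos, r.ref, r.alt, r.individual), []).append(
            (r.alt_reads, r.alt_reads + r.ref_reads)
        )

    n_tests = max(1, len(events)) * 2 * _PARENT_TISSUE_COUNT
    rows = []
    for ev in events:
        lead = ev.member_calls[0]
        key = (lead.chrom, lead.pos, lead.ref_allele, lead.alt_allele)
        carrier0 = sorted(ev.carrier_offspring)[0]
        father = pedigree.father_of(carrier0).id
        mother = pedigree.mother_of(carrier0).id
        carrier_counts = {}
        for cid in sorted(ev.carrier_offspring):
            counts = pooled_idx.get(key + (cid,))
            if counts is not None and counts[1] > 0:
                carrier_counts[cid] = counts
        if not carrier_counts:
            continue
        father_tissues = tissue_idx.get(key + (father,), [])
        mother_tissues = tissue_idx.get(key + (mother,), [])
        unrelated = [
            pooled_idx[key + (i.id,)]
            for i in pedigree.unrelated_to(carrier0)
            if key + (i.id,) in pooled_idx
        ]
        err = mutation_specific_error([(a, d) for a, d in unrelated]) if unrelated else None
        if err is None:
            err = 1e-4  # no unrelated data: fall back to a nominal error rate
        per_tissue = {
            cid: [
                TissueObservation("t%d" % k, d - a, a)
                for k, (a, d) in enumerate(tissue_idx.get(key + (cid,), []))
            ]
            for cid in carrier_counts
        }
        call = classify_event(
            ev,
            carrier_counts=carrier_counts,
            father_tissues=father_tissues,
            mother_tissues=mother_tissues,
            site_error=max(err, 1e-6),
            n_tests=n_tests,
            params=params,
            per_tissue_counts=per_tissue,
        )
        alt, depth = carrier_counts[sorted(carrier_counts)[0]]
        rows.append(
            {
                "event_id": ev.event_id,
                "chrom": ev.chrom,
                "pos": ev.pos,
                "ref": lead.ref_allele,
                "alt": lead.alt_allele,
                "stratum": call.stratum,
                "rate_stratum": call.rate_stratum,
                "delta_loglik": call.delta_loglik,
                "parent_fraction": call.parent_mosaic_fraction,
                "n_carriers": call.n_carriers,
                "origin": ev.parental_origin,
                "ho": call.ho,
                "carriers": ",".join(sorted(ev.carrier_offspring)),
                "vaf": alt / depth if depth else np.nan,
                "n_sites": ev.n_sites,
            }
        )
    return pd.DataFrame(rows)


def estimate_rates(
    strata: pd.DataFrame,
    pedigree: Pedigree,
    demography: GermlineDemography,
    genome_size: float,
    corrections: Optional[SensitivityCorrections] = None,
    vee_model: Optional[VEETransmissionModel] = None,
) -> tuple[RateSet, pd.DataFrame]:
    """Per-generation/year/cell-division rates from a strata table.

    Each offspring's count sums the events it carries, with VEE events
    weighted by the transmission model (weight 1 when no model is given);
    the sensitivity correction then scales the mean up.  Returns the rate
    set and the per-offspring count table.
    """
    corrections = corrections or SensitivityCorrections()
    offspring = sorted(
        (i.id for i in pedigree.offspring() if i.sequencing_tier == "wgs")
    )
    counts = {o: 0.0 for o in offspring}
    raw_counts = {o: 0 for o in offspring}
    for row in strata.itertuples(index=False):
        weight = 1.0
        if row.rate_stratum == "VEE" and vee_model is not None:
            # germline weight of one VEE event: 2 * clip(b0 + b1 * VAF, 0, 1)
            weight = adjusted_vee_count([min(row.vaf, 0.5)], vee_model)
        for cid in row.carriers.split(","):
            if cid in counts:
                counts[cid] += weight if row.rate_stratum == "VEE" else 1.0
                raw_counts[cid] += 1
    per_offspring = pd.DataFrame(
        {
            "individual": offspring,
            "count_weighted": [counts[o] for o in offspring],
            "count_raw": [raw_counts[o] for o in offspring],
        }
    )
    mean_weighted = per_offspring["count_weighted"].mean() if offspring else 0.0
    corrected = corrected_mean_mutations(mean_weighted, corrections)
    total_raw = int(per_offspring["count_raw"].sum())
    rates = rate_set(corrected, genome_size, demography, total_count=total_raw)
    return rates, per_offspring


@dataclass
class PipelineResult:
    strata: pd.DataFrame
    rates: RateSet
    per_offspring: pd.DataFrame
    spectrum: SpectrumProfile
    lineages: Optional[LineagePartition]
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    calls: pd.DataFrame,
    pedigree: Pedigree,
    demography: GermlineDemography,
    genome_size: float,
    *,
    filter_params: Optional[FilterParams] = None,
    classifier_params: Optional[ClassifierParams] = None,
    corrections: Optional[SensitivityCorrections] = None,
    vee_model: Optional[VEETransmissionModel] = None,
    mask: Optional[RegionMask] = None,
    filter_mode: str = "error-rate",
    lineage_p_threshold: float = 0.05,
    seed: int = 0,
) -> PipelineResult:
    """Filter -> classify -> rates/spectra/lineages on a call table."""
    retained, ledger = filter_offspring_candidates(
        calls, pedigree, filter_params, mask=mask, mode=filter_mode
    )
    events = build_events(retained, pedigree)
    strata = classify_events(events, calls, pedigree, classifier_params)

    rates, per_offspring = estimate_rates(
        strata, pedigree, demography, genome_size, corrections, vee_model
    )

    subs = (
        [(r.ref, r.alt) for r in strata.itertuples(index=False)]
        if len(strata)
        else []
    )
    prof = spectrum(subs)

    lineages = None
    shared = strata[strata["n_carriers"] >= 2] if len(strata) else strata
    if len(shared) >= 2:
        carriers = {
            r.event_id: set(r.carriers.split(",")) for r in shared.itertuples(index=False)
        }
        origins = {
            r.event_id: r.origin
            for r in shared.itertuples(index=False)
            if r.origin in ("paternal", "maternal")
        }
        offspring_ids = sorted(i.id for i in pedigree.offspring())
        matrix = SharingMatrix.from_carrier_sets(carriers, offspring_ids, origins)
        lineages = reconstruct_lineages(matrix, p_threshold=lineage_p_threshold)

    manifest = {
        "version": __version__,
        "seed": seed,
        "n_input_rows": int(len(calls)),
        "n_candidates_removed": int(len(ledger)),
        "n_events": int(len(strata)),
        "filter_mode": filter_mode,
        "demography": demography.species,
        "genome_size": genome_size,
        "strata_counts": (
            strata["rate_stratum"].value_counts().to_dict() if len(strata) else {}
        ),
    }
    return PipelineResult(
        strata=strata,
        rates=rates,
        per_offspring=per_offspring,
        spectrum=prof,
        lineages=lineages,
        manifest=manifest,
    )


def manifest_json(result: PipelineResult) -> str:
    return json.dumps(result.manifest, indent=2, sort_keys=True)
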
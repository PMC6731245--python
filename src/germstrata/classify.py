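"""Assignment of mutation events to temporal strata of the germline.

Four strata are distinguished from tissue-level allele fractions, parental
mosaicism tests and sibling sharing:

* ``VEE`` — very early embryonic: mosaic in the offspring (~25% of reads,
  i.e. ~50% of cells), absent from parents.
* ``EE`` — early embryonic: constitutive in offspring, detectably mosaic
  (2-20% of cells) in a parent's somatic tissues.
* ``peri_PGC`` — shared by two or more siblings but below the somatic
  detection floor (1.6% of cells) in both parents.
* ``late_post_PGC`` — constitutive in a single offspring.

The VEE/constitutive decision is a binomial log-likelihood contrast
(p = 0.25 vs p = 0.5) with a symmetric decision band; events inside the
band are unassigned and treated as late post-PGC downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .pedigree import MutationEvent, Pedigree, PhaseEvidence, TissueObservation

__all__ = [
    "STRATA",
    "StratumCall",
    "ClassifierParams",
    "MosaicTest",
    "vee_loglik_difference",
    "tissues_concordant",
    "haplotype_occupancy",
    "detect_parental_mosaic",
    "detection_power",
    "classify_event",
]

STRATA = ("VEE", "EE", "peri_PGC", "late_post_PGC", "unassigned")


@dataclass
class StratumCall:
    """Outcome of classifying one mutation event."""

    stratum: str
    delta_loglik: Optional[float] = None
    parent_mosaic_fraction: Optional[float] = None
    parent_mosaic_p: Optional[float] = None
    n_carriers: int = 1
    ho: Optional[float] = None

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")

    @property
    def rate_stratum(self) -> str:
        """Stratum used for rate work: unassigned relabels to late post-PGC."""
        return "late_post_PGC" if self.stratum == "unassigned" else self.stratum


@dataclass
class ClassifierParams:
    vee_delta_threshold: float = 5.0
    vee_p: float = 0.25
    constitutive_p: float = 0.5
    concordance_alpha: float = 0.01
    mosaic_alpha: float = 0.05
    detect_floor: float = 0.016  # cell fraction below which parental soma is "clean"
    require_all_tissues: bool = True


@dataclass
class MosaicTest:
    is_mosaic: bool
    fraction: Optional[float]  # cell fraction = 2 x pooled VAF
    p: Optional[float]


def vee_loglik_difference(
    alt: int,
    depth: int,
    threshold: float = 5.0,
    vee_p: float = 0.25,
    constitutive_p: float = 0.5,
) -> tuple[float, str]:
    """Binomial log-likelihood difference between the mosaic and constitutive
    models at the observed allele counts.

    Returns ``(delta, verdict)`` with ``delta = log L(p=0.25) - log L(p=0.5)``
    (the binomial coefficient cancels) and verdict ``"vee"`` when
    ``delta > threshold``, ``"constitutive"`` when ``delta < -threshold``,
    ``"unassigned"`` otherwise.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= alt <= depth:
        raise ValueError("alt must lie in [0, depth]")
    delta = (
        alt * (math.log(vee_p) - math.log(constitutive_p))
        + (depth - alt) * (math.log1p(-vee_p) - math.log1p(-constitutive_p))
    )
    if delta > threshold:
        verdict = "vee"
    elif delta < -threshold:
        verdict = "constitutive"
    else:
        verdict = "unassigned"
    return delta, verdict


def tissues_concordant(
    observations: Sequence[TissueObservation], alpha: float = 0.01
) -> bool:
    """Test that allele ratios agree across tissues before pooling.

    Uses Fisher's exact test for two tissues and a chi-squared contingency
    test for more; tissues with zero depth are ignored.  Returns True when
    there is no evidence of discordance at level ``alpha``.
    """
    usable = [o for o in observations if o.depth > 0]
    if len(usable) < 2:
        return True
    table = [[o.alt_reads for o in usable], [o.ref_reads for o in usable]]
    if len(usable) == 2:
        _, p = stats.fisher_exact(
            [[table[0][0], table[0][1]], [table[1][0], table[1][1]]],
            alternative="two-sided",
        )
    else:
        if sum(table[0]) == 0 or sum(table[1]) == 0:
            return True
        _, p, _, _ = stats.chi2_contingency(table)
    return p >= alpha


def haplotype_occupancy(phase: PhaseEvidence) -> Optional[float]:
    """Fraction of origin-haplotype read pairs carrying the derived allele.

    1.0 for constitutive (pre-embryonic) mutations, < 1 for post-zygotic
    ones.  Undefined (``None``) when there are no informative pairs.
    """
    if phase.informative_pairs_total == 0:
        return None
    return phase.informative_pairs_with_alt / phase.informative_pairs_total


def _mosaic_threshold(p_cut: float, depth: int, site_error: float) -> int:
    """Smallest alt count whose upper-tail binomial p-value beats ``p_cut``."""
    # isf on the binomial survival function: P(X >= k) = sf(k - 1)
    k = int(stats.binom.isf(p_cut, depth, site_error)) + 1
    while k > 0 and stats.binom.sf(k - 2, depth, site_error) < p_cut:
        k -= 1
    return k


def detect_parental_mosaic(
    tissue_counts: Sequence[tuple[int, int]],
    site_error: float,
    n_tests: int,
    alpha: float = 0.05,
    detect_floor: float = 0.016,
    require_all_tissues: bool = True,
) -> MosaicTest:
    """Test a parent for somatic mosaicism at a mutation site.

    ``tissue_counts`` is a sequence of ``(alt, depth)`` per tissue.  Each
    tissue gets an upper-tail binomial p-value against the site-specific
    error rate; the site is mosaic when the Bonferroni-corrected criterion
    (``alpha / n_tests``) is met — by every non-empty tissue when
    ``require_all_tissues``, else by at least one — and the implied cell
    fraction (2 x pooled VAF) reaches ``detect_floor``.
    """
    usable = [(a, d) for a, d in tissue_counts if d > 0]
    if not usable:
        raise ValueError("all tissues have zero depth")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    pvals = [float(stats.binom.sf(a - 1, d, site_error)) for a, d in usable]
    pooled_alt = sum(a for a, _ in usable)
    pooled_depth = sum(d for _, d in usable)
    fraction = 2.0 * pooled_alt / pooled_depth
    cut = alpha / n_tests
    significant = [p < cut for p in pvals]
    hit = all(significant) if require_all_tissues else any(significant)
    is_mosaic = hit and fraction >= detect_floor
    return MosaicTest(is_mosaic=is_mosaic, fraction=fraction, p=min(pvals))


def detection_power(
    depth: int,
    mosaic_level: float,
    site_error: float,
    n_tests: int,
    alpha: float = 0.05,
) -> float:
    """Probability that a single-tissue mosaicism test fires when the true
    cell fraction is ``mosaic_level`` (expected VAF = level / 2), by exact
    enumeration over alt-read counts."""
    if depth <= 0:
        return 0.0
    k_min = _mosaic_threshold(alpha / n_tests, depth, site_error)
    if k_min > depth:
        return 0.0
    return float(stats.binom.sf(k_min - 1, depth, mosaic_level / 2.0))


def classify_event(
    event: MutationEvent,
    *,
    carrier_counts: dict[str, tuple[int, int]],
    father_tissues: Sequence[tuple[int, int]],
    mother_tissues: Sequence[tuple[int, int]],
    site_error: float,
    n_tests: int,
    params: Optional[ClassifierParams] = None,
    per_tissue_counts: Optional[dict[str, Sequence[TissueObservation]]] = None,
) -> StratumCall:
    """Assign one event to a temporal stratum.

    ``carrier_counts`` maps each carrier offspring id to pooled
    ``(alt, depth)``; ``father_tissues``/``mother_tissues`` give per-tissue
    ``(alt, depth)`` for the two parents.  Precedence: parental mosaicism
    above the detection floor wins (EE); otherwise >= 2 carriers with clean
    parental soma is peri-PGC; otherwise the single-carrier binomial
    contrast decides VEE vs constitutive (late post-PGC).  Phase evidence
    (haplotype occupancy) is carried along but never overrides the
    likelihood verdict.
    """
    params = params or ClassifierParams()
    if not carrier_counts:
        raise ValueError("event has no carriers")

    ho = None
    origin = event.parental_origin
    for call in event.member_calls:
        if call.phase is not None:
            ho = haplotype_occupancy(call.phase)
            if call.phase.origin != "unknown":
                origin = call.phase.origin
            break

    mosaic_by_parent: dict[str, MosaicTest] = {}
    for label, tissues in (("paternal", father_tissues), ("maternal", mother_tissues)):
        usable = [(a, d) for a, d in tissues if d > 0]
        if usable:
            mosaic_by_parent[label] = detect_parental_mosaic(
                usable,
                site_error,
                n_tests,
                alpha=params.mosaic_alpha,
                detect_floor=params.detect_floor,
                require_all_tissues=params.require_all_tissues,
            )

    n_carriers = len(carrier_counts)
    hits = {lab: t for lab, t in mosaic_by_parent.items() if t.is_mosaic}
    if hits:
        label, test = min(hits.items(), key=lambda kv: kv[1].p)
        event.parental_origin = label
        call = StratumCall(
            stratum="EE",
            parent_mosaic_fraction=test.fraction,
            parent_mosaic_p=test.p,
            n_carriers=n_carriers,
            ho=ho,
        )
        event.stratum = call
        return call

    max_parent_fraction = max(
        (t.fraction for t in mosaic_by_parent.values() if t.fraction is not None),
        default=0.0,
    )
    if n_carriers >= 2 and max_parent_fraction < params.detect_floor:
        call = StratumCall(
            stratum="peri_PGC",
            parent_mosaic_fraction=max_parent_fraction,
            n_carriers=n_carriers,
            ho=ho,
        )
        event.parental_origin = origin
        event.stratum = call
        return call

    # Single constitutive carrier (or shared with residual parental signal):
    # pool across tissues after a concordance check, then run the contrast.
    carrier_id = event.individual_id if event.individual_id in carrier_counts else next(iter(carrier_counts))
    alt, depth = carrier_counts[carrier_id]
    if per_tissue_counts and carrier_id in per_tissue_counts:
        if not tissues_concordant(per_tissue_counts[carrier_id], params.concordance_alpha):
            call = StratumCall(stratum="unassigned", n_carriers=n_carriers, ho=ho)
            event.stratum = call
            return call
    delta, verdict = vee_loglik_difference(
        alt,
        depth,
        threshold=params.vee_delta_threshold,
        vee_p=params.vee_p,
        constitutive_p=params.constitutive_p,
    )
    if n_carriers >= 2:
        # shared mutations are constitutive by definition
        stratum = "peri_PGC"
    elif verdict == "vee":
        stratum = "VEE"
    elif verdict == "constitutive":
        stratum = "late_post_PGC"
    else:
        stratum = "unassigned"
    call = StratumCall(stratum=stratum, delta_loglik=delta, n_carriers=n_carriers, ho=ho)
    event.parental_origin = origin
    event.stratum = call
    return call
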
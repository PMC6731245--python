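"""Mutation-rate estimation: sensitivity-corrected counts, per-generation /
per-year / per-cell-division rates with exact Poisson intervals, the VEE
germline-contribution adjustment, stage-specific per-division rates, the
parental-age effect and the VEE over-dispersion test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SensitivityCorrections",
    "GermlineDemography",
    "MOUSE",
    "HUMAN",
    "RateSet",
    "VEETransmissionModel",
    "OverdispersionResult",
    "AgeEffect",
    "poisson_ci",
    "corrected_mean_mutations",
    "rate_set",
    "fit_vee_transmission",
    "adjusted_vee_count",
    "stage_rates",
    "fit_age_effect",
    "overdispersion_test",
    "compare_rate_samples",
    "compare_rate_estimates",
    "bonferroni",
]


@dataclass(frozen=True)
class SensitivityCorrections:
    """Proportions of the genome/callset effectively interrogated."""

    p_depth: float = 1.0
    p_filter: float = 1.0
    p_dnm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_depth", "p_filter", "p_dnm"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")

    @property
    def product(self) -> float:
        return self.p_depth * self.p_filter * self.p_dnm


@dataclass(frozen=True)
class GermlineDemography:
    """Per-species germline cellular demography (after Drost & Lee)."""

    species: str
    generation_time_years: float
    divisions_paternal: float
    divisions_maternal: float
    age_at_puberty_years: float
    ssc_divisions_per_year: float

    def __post_init__(self) -> None:
        for f in (
            "generation_time_years",
            "divisions_paternal",
            "divisions_maternal",
            "age_at_puberty_years",
            "ssc_divisions_per_year",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def total_divisions(self) -> float:
        return self.divisions_paternal + self.divisions_maternal

    @property
    def replication_ratio(self) -> float:
        """Paternal:maternal ratio of germline genome replications."""
        return self.divisions_paternal / self.divisions_maternal

    def pre_puberty_divisions_paternal(self) -> float:
        """Male germline divisions before puberty: the per-generation
        paternal total minus SSC divisions accrued between puberty and the
        assumed generation time."""
        post = self.ssc_divisions_per_year * (
            self.generation_time_years - self.age_at_puberty_years
        )
        pre = self.divisions_paternal - post
        if pre <= 0:
            raise ValueError("demography implies no pre-puberty divisions")
        return pre


MOUSE = GermlineDemography("mouse", 0.75, 62, 25, 1.0 / 12.0, 42)
HUMAN = GermlineDemography("human", 30.0, 401, 31, 15.0, 23)


@dataclass
class RateSet:
    mu_generation: float
    mu_year: float
    mu_cell_division: float
    ci_generation: tuple[float, float]
    ci_year: tuple[float, float]
    ci_cell_division: tuple[float, float]
    mean_mutations: float
    genome_size: float
    demography: GermlineDemography


@dataclass
class VEETransmissionModel:
    beta0: float
    beta1: float
    pearson_r: float

    def predict(self, vaf: float) -> float:
        return float(np.clip(self.beta0 + self.beta1 * vaf, 0.0, 1.0))


@dataclass
class OverdispersionResult:
    phi: float
    p_value: float


@dataclass
class AgeEffect:
    slope_per_year: float
    p_value: float
    intercept: float
    slope_se: float


def poisson_ci(count: float, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood, chi-square) confidence interval for a Poisson mean."""
    if count < 0:
        raise ValueError("count must be >= 0")
    a = 1.0 - conf
    lo = 0.0 if count == 0 else stats.chi2.ppf(a / 2.0, 2.0 * count) / 2.0
    hi = stats.chi2.ppf(1.0 - a / 2.0, 2.0 * count + 2.0) / 2.0
    return float(lo), float(hi)


def corrected_mean_mutations(m: float, corr: SensitivityCorrections) -> float:
    """Scale the mean observed mutations per offspring up by the fraction of
    the genome/callset interrogated."""
    if m < 0:
        raise ValueError("mean mutation count must be >= 0")
    if corr.product <= 0:
        raise ValueError("correction product must be positive")
    return m / corr.product


def rate_set(
    corrected_mean: float,
    genome_size: float,
    demography: GermlineDemography,
    total_count: Optional[float] = None,
) -> RateSet:
    """Per-generation / per-year / per-cell-division haploid rates.

    ``corrected_mean`` is the (sensitivity-corrected, VEE-weighted) mean
    diploid mutation count per offspring.  The 95% interval comes from an
    exact Poisson interval on ``total_count`` (the summed raw event count
    across offspring), propagated linearly; when ``total_count`` is omitted
    the interval collapses onto the point estimate.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if corrected_mean < 0:
        raise ValueError("corrected_mean must be >= 0")
    mu_gen = corrected_mean / genome_size / 2.0
    mu_year = mu_gen / demography.generation_time_years
    mu_cd = mu_gen / (demography.total_divisions / 2.0)

    if total_count is not None and total_count > 0:
        lo, hi = poisson_ci(total_count)
        lo_f, hi_f = lo / total_count, hi / total_count
    elif total_count == 0:
        # all-zero data: rates are zero with a zero lower bound
        return RateSet(
            0.0, 0.0, 0.0, (0.0, 0.0), (0.0, 0.0), (0.0, 0.0),
            corrected_mean, genome_size, demography,
        )
    else:
        lo_f, hi_f = 1.0, 1.0

    return RateSet(
        mu_generation=mu_gen,
        mu_year=mu_year,
        mu_cell_division=mu_cd,
        ci_generation=(mu_gen * lo_f, mu_gen * hi_f),
        ci_year=(mu_year * lo_f, mu_year * hi_f),
        ci_cell_division=(mu_cd * lo_f, mu_cd * hi_f),
        mean_mutations=corrected_mean,
        genome_size=genome_size,
        demography=demography,
    )


def fit_vee_transmission(
    pairs: Sequence[tuple[float, float]]
) -> VEETransmissionModel:
    """Ordinary least squares of offspring transmission proportion on
    parental somatic VAF."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 (VAF, proportion) pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("parental VAFs are constant; slope is unidentifiable")
    res = stats.linregress(x, y)
    return VEETransmissionModel(
        beta0=float(res.intercept), beta1=float(res.slope), pearson_r=float(res.rvalue)
    )


def adjusted_vee_count(
    vafs: Sequence[float], model: VEETransmissionModel
) -> float:
    """Germline-weighted VEE count: ``2 * sum_j clip(b0 + b1 * VAF_j, 0, 1)``."""
    total = 0.0
    for v in vafs:
        if not 0.0 <= v <= 0.5:
            raise ValueError("VEE VAFs must lie in [0, 0.5]")
        total += model.predict(v)
    return 2.0 * total


def _quasi_poisson_ci(
    counts: np.ndarray, conf: float = 0.95
) -> tuple[float, float, float]:
    """Mean and interval ``mean +/- z * sqrt(phi * mean / n)`` where phi is
    the Pearson dispersion; returns (mean, lo, hi)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    mean = counts.mean()
    if mean == 0:
        return 0.0, 0.0, 0.0
    phi = max(1.0, float(((counts - mean) ** 2 / mean).sum() / max(n - 1, 1)))
    z = stats.norm.ppf(0.5 + conf / 2.0)
    half = z * np.sqrt(phi * mean / n)
    return float(mean), float(max(0.0, mean - half)), float(mean + half)


@dataclass
class StageRate:
    stage: str
    rate: float
    ci: Optional[tuple[float, float]] = None


def stage_rates(
    *,
    demography: GermlineDemography,
    genome_size: float,
    mean_total: float,
    total_count: Optional[float] = None,
    vee_counts: Optional[Sequence[int]] = None,
    mean_vee: Optional[float] = None,
    frac_paternal_phased: Optional[float] = None,
    annual_slope: Optional[float] = None,
    annual_slope_se: Optional[float] = None,
    age_mean_years: Optional[float] = None,
) -> dict[str, StageRate]:
    """Stage-specific haploid mutation rates per base per cell division.

    Computes whichever of the following the inputs permit: the sex-averaged
    rate; paternal/maternal averages (the mean count scaled by the phased
    paternal fraction over each sex's division count); the VEE first-
    cleavage rate (quasi-Poisson interval over ``vee_counts``); pre-puberty
    male rate (the mean count minus the post-puberty accrual
    ``(age_mean - age_puberty) * annual_slope``, over pre-puberty
    divisions); and post-puberty male rate (annual slope over SSC divisions
    per year).
    """
    out: dict[str, StageRate] = {}
    G = genome_size

    avg = mean_total / G / demography.total_divisions  # = mu_gen / (div/2), halved
    ci = None
    if total_count is not None and total_count > 0:
        lo, hi = poisson_ci(total_count)
        ci = (avg * lo / total_count, avg * hi / total_count)
    out["average"] = StageRate("average", avg, ci)

    if frac_paternal_phased is not None:
        pat_mean = mean_total * frac_paternal_phased
        mat_mean = mean_total * (1.0 - frac_paternal_phased)
        out["paternal"] = StageRate(
            "paternal", pat_mean / demography.divisions_paternal / G
        )
        out["maternal"] = StageRate(
            "maternal", mat_mean / demography.divisions_maternal / G
        )

    if vee_counts is not None or mean_vee is not None:
        if vee_counts is not None:
            m, lo, hi = _quasi_poisson_ci(np.asarray(vee_counts))
            out["VEE"] = StageRate("VEE", m / G / 2.0, (lo / G / 2.0, hi / G / 2.0))
        else:
            out["VEE"] = StageRate("VEE", mean_vee / G / 2.0)

    if annual_slope is not None and age_mean_years is not None:
        if age_mean_years < demography.age_at_puberty_years:
            raise ValueError("mean parental age below puberty age")
        n_pre = mean_total - (
            age_mean_years - demography.age_at_puberty_years
        ) * annual_slope
        d_pre = demography.pre_puberty_divisions_paternal()
        out["pre_puberty"] = StageRate("pre_puberty", n_pre / G / d_pre / 2.0)

    if annual_slope is not None:
        rate = annual_slope / demography.ssc_divisions_per_year / G
        ci = None
        if annual_slope_se is not None:
            z = stats.norm.ppf(0.975)
            ci = (
                max(0.0, (annual_slope - z * annual_slope_se))
                / demography.ssc_divisions_per_year
                / G,
                (annual_slope + z * annual_slope_se)
                / demography.ssc_divisions_per_year
                / G,
            )
        out["post_puberty"] = StageRate("post_puberty", rate, ci)

    return out


def fit_age_effect(
    counts: Sequence[float],
    ages_years: Sequence[float],
    pedigree_ids: Sequence[str],
) -> AgeEffect:
    """Linear model of per-offspring mutation count on parental age with a
    per-pedigree random intercept (REML); falls back to plain OLS when only
    one pedigree is present."""
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages_years, dtype=float)
    groups = np.asarray(pedigree_ids)
    if len(set(ages.tolist())) < 2:
        raise ValueError("need at least two distinct ages")
    exog = sm.add_constant(ages)
    if len(set(groups.tolist())) > 1:
        model = sm.MixedLM(counts, exog, groups=groups)
        try:
            fit = model.fit(reml=True)
            return AgeEffect(
                slope_per_year=float(fit.params[1]),
                p_value=float(fit.pvalues[1]),
                intercept=float(fit.params[0]),
                slope_se=float(fit.bse[1]),
            )
        except (np.linalg.LinAlgError, ValueError):
            pass  # singular random-effects fit: use fixed intercepts below
        df = pd.DataFrame({"y": counts, "age": ages, "ped": groups})
        fit = sm.OLS.from_formula("y ~ age + C(ped)", data=df).fit()
        return AgeEffect(
            slope_per_year=float(fit.params["age"]),
            p_value=float(fit.pvalues["age"]),
            intercept=float(fit.params["Intercept"]),
            slope_se=float(fit.bse["age"]),
        )
    fit = sm.OLS(counts, exog).fit()
    return AgeEffect(
        slope_per_year=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
    )


def overdispersion_test(
    counts: Sequence[int],
    n_boot: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> OverdispersionResult:
    """Parametric-bootstrap test of Poisson over-dispersion.

    The statistic is the Pearson dispersion ``phi = chi2 / (n - 1)`` around
    the observed mean; the p-value is the fraction of Poisson bootstrap
    replicates (same n, same mean) with dispersion at least as large.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    if n < 5:
        raise ValueError("need at least 5 offspring")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("all counts are zero")
    rng = rng or np.random.default_rng()
    phi = float(((counts - mean) ** 2 / mean).sum() / (n - 1))
    sims = rng.poisson(mean, size=(n_boot, n)).astype(float)
    sim_means = sims.mean(axis=1)
    sim_means[sim_means == 0] = np.nan
    sim_phi = ((sims - sim_means[:, None]) ** 2 / sim_means[:, None]).sum(axis=1) / (
        n - 1
    )
    p = float((np.nansum(sim_phi >= phi) + 1) / (n_boot + 1))
    return OverdispersionResult(phi=phi, p_value=p)


def bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


def compare_rate_samples(
    samples: dict[str, Sequence[float]]
) -> pd.DataFrame:
    """Pairwise rank and t tests between count samples, Bonferroni-adjusted
    over the whole comparison family."""
    names = sorted(samples)
    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    for a, b in pairs:
        xa = np.asarray(samples[a], dtype=float)
        xb = np.asarray(samples[b], dtype=float)
        if np.array_equal(xa, xb):
            p_rank, p_t = 1.0, 1.0
        else:
            p_rank = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            p_t = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
            if np.isnan(p_t):
                p_t = 1.0
        rows.append(
            {
                "a": a,
                "b": b,
                "p_rank": p_rank,
                "p_t": p_t,
                "p_rank_adj": bonferroni(p_rank, m),
                "p_t_adj": bonferroni(p_t, m),
            }
        )
    return pd.DataFrame(rows)


def compare_rate_estimates(
    estimates: dict[str, tuple[float, tuple[float, float]]]
) -> pd.DataFrame:
    """Pairwise z/t tests between ``mean, (lo, hi)`` estimates, with the SE
    implied by the 95% interval width; Bonferroni-adjusted."""
    z95 = stats.norm.ppf(0.975)
    names = sorted(estimates)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        ma, (loa, hia) = estimates[a]
        mb, (lob, hib) = estimates[b]
        se = np.hypot((hia - loa) / (2 * z95), (hib - lob) / (2 * z95))
        if se == 0:
            p = 1.0 if ma == mb else 0.0
        else:
            p = float(2 * stats.norm.sf(abs(ma - mb) / se))
        rows.append({"a": a, "b": b, "p": p, "p_adj": bonferroni(p, m)})
    return pd.DataFrame(rows)
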
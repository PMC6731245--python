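"""Seven-category mutation spectra and chi-squared spectrum comparison.

Mutations are strand-collapsed to the six distinguishable point-mutation
classes, with the C:G>T:A transition class split by CpG context of the
mutated cytosine on either strand — giving seven categories in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CATEGORIES",
    "SpectrumProfile",
    "classify_substitution",
    "spectrum",
    "compare_spectra",
    "category_tests",
]

CATEGORIES = (
    "C:G>T:A_CpG",
    "C:G>T:A_nonCpG",
    "T:A>C:G",
    "C:G>A:T",
    "C:G>G:C",
    "T:A>A:T",
    "T:A>G:C",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# pyrimidine-ref class labels
_CLASS = {
    ("C", "T"): "C:G>T:A",
    ("C", "A"): "C:G>A:T",
    ("C", "G"): "C:G>G:C",
    ("T", "C"): "T:A>C:G",
    ("T", "A"): "T:A>A:T",
    ("T", "G"): "T:A>G:C",
}


def classify_substitution(
    ref: str,
    alt: str,
    context_5prime: Optional[str] = None,
    context_3prime: Optional[str] = None,
    cpg_split_class: str = "C:G>T:A",
) -> str:
    """Map one substitution (with flanking context) to its spectrum category.

    Purine references are reverse-complemented onto the pyrimidine strand
    (which swaps and complements the flanks).  For the class named by
    ``cpg_split_class`` the result is suffixed ``_CpG`` when the mutated C
    sits in a CpG dinucleotide on either strand, ``_nonCpG`` otherwise;
    unknown 3' context counts as non-CpG.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context_5prime, context_3prime = (
            _COMPLEMENT.get(context_3prime) if context_3prime else None,
            _COMPLEMENT.get(context_5prime) if context_5prime else None,
        )
    label = _CLASS[(ref, alt)]
    if label == cpg_split_class:
        is_cpg = ref == "C" and context_3prime == "G"
        return f"{label}_{'CpG' if is_cpg else 'nonCpG'}"
    return label


@dataclass
class SpectrumProfile:
    counts: dict[str, int]
    total: int
    proportions: dict[str, float]
    ci95: dict[str, tuple[float, float]]

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CATEGORIES], dtype=float)


def spectrum(
    substitutions: Sequence[tuple],
    cpg_split_class: str = "C:G>T:A",
) -> SpectrumProfile:
    """Build a spectrum profile from ``(ref, alt[, ctx5, ctx3])`` tuples.

    Per-category 95% intervals are Clopper-Pearson binomial intervals on
    the category proportion; proportions are NaN on empty input.
    """
    if cpg_split_class not in set(_CLASS.values()):
        raise ValueError(f"unknown class {cpg_split_class!r}")
    cats = _categories_for(cpg_split_class)
    counts = {c: 0 for c in cats}
    for sub in substitutions:
        ref, alt = sub[0], sub[1]
        c5 = sub[2] if len(sub) > 2 else None
        c3 = sub[3] if len(sub) > 3 else None
        counts[classify_substitution(ref, alt, c5, c3, cpg_split_class)] += 1
    total = sum(counts.values())
    if total == 0:
        props = {c: float("nan") for c in cats}
        cis = {c: (float("nan"), float("nan")) for c in cats}
    else:
        props = {c: counts[c] / total for c in cats}
        cis = {}
        for c in cats:
            k = counts[c]
            lo = 0.0 if k == 0 else stats.beta.ppf(0.025, k, total - k + 1)
            hi = 1.0 if k == total else stats.beta.ppf(0.975, k + 1, total - k)
            cis[c] = (float(lo), float(hi))
    return SpectrumProfile(counts=counts, total=total, proportions=props, ci95=cis)


def _categories_for(cpg_split_class: str) -> tuple[str, ...]:
    cats = []
    for base in dict.fromkeys(_CLASS.values()):
        if base == cpg_split_class:
            cats += [f"{base}_CpG", f"{base}_nonCpG"]
        else:
            cats.append(base)
    return tuple(cats)


def compare_spectra(
    a: SpectrumProfile, b: SpectrumProfile
) -> tuple[float, int, float]:
    """Chi-squared comparison of two spectra as a 2 x 7 contingency table.

    Degrees of freedom are fixed at 6; categories absent from both spectra
    are pooled out of the table (the p-value still uses df = 6).
    """
    if a.total == 0 or b.total == 0:
        raise ValueError("both spectra need at least one mutation")
    if set(a.counts) != set(b.counts):
        raise ValueError("spectra use different category sets")
    cats = list(a.counts)
    table = np.array(
        [[a.counts[c] for c in cats], [b.counts[c] for c in cats]], dtype=float
    )
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = 6
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def category_tests(a: SpectrumProfile, b: SpectrumProfile) -> dict[str, float]:
    """Per-category two-proportion z-tests, Bonferroni-adjusted over the
    category family."""
    cats = list(a.counts)
    m = len(cats)
    out = {}
    for c in cats:
        k1, k2 = a.counts[c], b.counts[c]
        n1, n2 = a.total, b.total
        pool = (k1 + k2) / (n1 + n2)
        if pool in (0.0, 1.0):
            out[c] = 1.0
            continue
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        z = (k1 / n1 - k2 / n2) / se
        out[c] = min(1.0, m * float(2 * stats.norm.sf(abs(z))))
    return out
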
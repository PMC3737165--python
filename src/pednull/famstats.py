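"""Summary statistics and the family-ratio mixture error estimator.

Null alleles segregating from shared grandparents should appear at similar
rates in the two related families, whereas genotyping errors turned out to
be strongly enriched in one family. Treating a null-allele class as a
mixture of true nulls (family ratio 1) and a fraction ``x`` of
different-homozygote genotyping errors (family ratio ``r_e``), the
observed family-1 : family-2 ratio of a class is

    r = (1 - x) + x * r_e

so the error fraction can be estimated as

    x = (r - 1) / (r_e - 1)

for classes enriched in family 1 (r >= 1), provided the error category is
itself enriched (r_e > 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .classify import (
    CATEGORIES,
    ERROR_CATEGORIES,
    IntegratedClassification,
    NULL_CLASSES,
)

TABLE_CATEGORIES = NULL_CLASSES + ERROR_CATEGORIES


@dataclass(frozen=True)
class MixtureEstimate:
    """Mixture-model decomposition of a null-allele class.

    ``x`` is the estimated fraction of the class attributable to
    genotyping error, in [0, 1]; None when the estimate is unavailable
    (class not family-1 enriched, or error category not enriched).
    """

    r: float
    re: float
    x: Optional[float]

    @property
    def percent(self) -> Optional[int]:
        return None if self.x is None else round(100 * self.x)


def mixture_error_fraction(r: float, re: float) -> MixtureEstimate:
    """Estimate the genotyping-error fraction of a class from family ratios."""
    if re <= 1 or r < 1:
        return MixtureEstimate(r=r, re=re, x=None)
    return MixtureEstimate(r=r, re=re, x=(r - 1) / (re - 1))


def implied_ratio(x: float, re: float) -> float:
    """Family ratio implied by an error fraction ``x`` (the forward model)."""
    return (1 - x) + x * re


@dataclass
class CategoryRow:
    category: str
    n_family1: int
    n_family2: int
    n_overall: int
    pct_both: Optional[float]  # % of overall SNPs with evidence in both families
    ratio: Optional[float]  # family1 / family2; None when family2 count is 0
    estimate: Optional[MixtureEstimate] = None

    @property
    def pct_error(self) -> Optional[int]:
        return None if self.estimate is None else self.estimate.percent


@dataclass
class SummaryTable:
    rows: list[CategoryRow]
    family_labels: tuple[str, str]
    n_markers: int

    def row(self, category: str) -> CategoryRow:
        for r in self.rows:
            if r.category == category:
                return r
        raise KeyError(category)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "category": r.category,
                    "family1": r.n_family1,
                    "family2": r.n_family2,
                    "overall": r.n_overall,
                    "pct_both_families": (
                        None if r.pct_both is None else round(r.pct_both)
                    ),
                    "ratio_family1_to_family2": (
                        None if r.ratio is None else round(r.ratio, 1)
                    ),
                    "estimated_pct_error": r.pct_error,
                }
            )
        return pd.DataFrame.from_records(recs)


def summarize(
    classifications: list[IntegratedClassification],
    family_labels: Optional[tuple[str, str]] = None,
) -> SummaryTable:
    """Tabulate per-family and integrated counts per category.

    Per-family counts come from the per-family classifications, overall
    counts from the integrated category. The both-families percentage is,
    for a null class, the share of its integrated SNPs with null-allele
    evidence in both families; for an error category, the share with
    errors in both families. Family ratios are computed from the
    per-family counts (before integration), and the mixture estimator is
    applied to every family-1-enriched null class using the
    different-homozygotes error ratio as ``r_e``.
    """
    if family_labels is None:
        labels = []
        for ic in classifications:
            for fc in ic.per_family:
                if fc.family_label not in labels:
                    labels.append(fc.family_label)
        if len(labels) != 2:
            raise ValueError(
                f"expected classifications from exactly 2 families, got {labels!r}"
            )
        family_labels = (labels[0], labels[1])
    lab1, lab2 = family_labels

    fam_counts = {lab: dict.fromkeys(CATEGORIES, 0) for lab in family_labels}
    overall = dict.fromkeys(CATEGORIES, 0)
    both = dict.fromkeys(CATEGORIES, 0)
    for ic in classifications:
        overall[ic.category] += 1
        for fc in ic.per_family:
            if fc.family_label in fam_counts:
                fam_counts[fc.family_label][fc.category] += 1
        cats = {fc.family_label: fc.category for fc in ic.per_family}
        if len(cats) >= 2:
            if ic.category in NULL_CLASSES:
                if all(c in NULL_CLASSES for c in cats.values()):
                    both[ic.category] += 1
            elif ic.category in ERROR_CATEGORIES:
                if all(c in ERROR_CATEGORIES for c in cats.values()):
                    both[ic.category] += 1

    err_row_counts = (
        fam_counts[lab1]["err_diffhom"],
        fam_counts[lab2]["err_diffhom"],
    )
    re = (
        err_row_counts[0] / err_row_counts[1] if err_row_counts[1] > 0 else None
    )

    rows: list[CategoryRow] = []
    for cat in TABLE_CATEGORIES:
        n1, n2 = fam_counts[lab1][cat], fam_counts[lab2][cat]
        n_all = overall[cat]
        ratio = n1 / n2 if n2 > 0 else None
        estimate = None
        if cat in NULL_CLASSES and ratio is not None and re is not None:
            est = mixture_error_fraction(ratio, re)
            if est.x is not None:
                estimate = est
        rows.append(
            CategoryRow(
                category=cat,
                n_family1=n1,
                n_family2=n2,
                n_overall=n_all,
                pct_both=100 * both[cat] / n_all if n_all > 0 else None,
                ratio=ratio,
                estimate=estimate,
            )
        )
    return SummaryTable(
        rows=rows, family_labels=family_labels, n_markers=len(classifications)
    )


def overall_percentages(table: SummaryTable, n_markers: int) -> tuple[float, float]:
    """Headline percentages: (null%, error%), one decimal each.

    Class 4 proved the least reliable null class (estimated 60% error), so
    it is counted with the error categories: null% covers classes 1, 2, 3
    and 5; error% covers class 4 plus both error categories.
    """
    null_n = sum(
        table.row(c).n_overall for c in ("class1", "class2", "class3", "class5")
    )
    err_n = sum(table.row(c).n_overall for c in ("class4",) + ERROR_CATEGORIES)
    return (
        round(100 * null_n / n_markers, 1),
        round(100 * err_n / n_markers, 1),
    )
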
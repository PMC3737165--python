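"""Five-class null-allele classification and two-family integration.

Each SNP x family configuration is placed into exactly one category:

* ``class1`` — more than one incompatibility, not explainable by a single
  genotyping error;
* ``class2`` — more than one incompatibility, explainable by one error;
* ``class3`` — a single incompatibility between an F1 parent and an F0
  grandparent where no further incompatibilities are expected (both F1
  parents called the same homozygote);
* ``class4`` — a single incompatibility where more would be expected if a
  null allele were segregating;
* ``class5`` — more than ``min_missing`` F2 offspring missing with both
  parents homozygous or missing, or both homozygotes but no heterozygote
  among the offspring with one parent missing and the other heterozygous
  (a parent carrying two null alleles);
* ``err_diffhom`` / ``err_other`` — incompatibilities with no consistent
  null-allele explanation, split by whether any parent-offspring pair was
  called as different homozygotes;
* ``consistent`` — none of the above.

Classes 1-4 additionally require the whole three-generation configuration
to admit a null-allele hypothesis (including the grandparent filter).
SNPs classified in two families are merged into an overall category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .pedmodel import CallMatrix, Family, Individual, Marker, is_het, is_hom
from .nullscan import (
    Incompatibility,
    NullHypothesis,
    find_incompatibilities,
    min_error_explanation,
    null_consistent,
)

NULL_CLASSES = ("class1", "class2", "class3", "class4", "class5")
ERROR_CATEGORIES = ("err_diffhom", "err_other")
CATEGORIES = NULL_CLASSES + ERROR_CATEGORIES + ("consistent",)


@dataclass
class SNPFamilyClassification:
    marker_id: str
    family_label: str
    category: str
    hypotheses: list[NullHypothesis] = field(default_factory=list)
    incompatibilities: list[Incompatibility] = field(default_factory=list)
    n_missing_f2: int = 0
    missing_f2: frozenset[str] = frozenset()

    @property
    def n_incompatibilities(self) -> int:
        return len(self.incompatibilities)

    @property
    def is_null_class(self) -> bool:
        return self.category in NULL_CLASSES


@dataclass
class IntegratedClassification:
    marker_id: str
    category: str
    per_family: list[SNPFamilyClassification]
    both_families: bool

    def family_result(self, label: str) -> Optional[SNPFamilyClassification]:
        for fc in self.per_family:
            if fc.family_label == label:
                return fc
        return None


def expected_more_incompatibilities(
    hypothesis: NullHypothesis,
    family: Family,
    marker: Marker,
    matrix: CallMatrix,
) -> bool:
    """Would a null allele in the hypothesised carrier be expected to
    produce further incompatibilities among the F2?

    True when the co-parent carries an allele differing from the carrier's
    visible allele: an F2 inheriting the null plus that allele would be
    called homozygous-incompatible with the carrier. False in the class-3
    configuration where both F1 parents share the same homozygous call.
    """
    carrier_ids = set(hypothesis.carrier_parent_ids)
    for par in family.parents:
        if par.id not in carrier_ids:
            continue
        visible = [a for pid, t in hypothesis.carriers if pid == par.id for a in t if a != 0]
        if not visible:
            continue  # two-null carrier: every offspring call is informative anyway
        co = [p for p in family.parents if p.id != par.id][0]
        co_call = matrix.get(marker.id, co.id)
        if co_call is None:
            return True
        if any(a != visible[0] for a in co_call):
            return True
    return False


def _class5_missing_pattern(
    matrix: CallMatrix,
    family: Family,
    marker: Marker,
    roster: dict[str, Individual],
    min_missing: int,
) -> bool:
    """Many missing F2 with both parents homozygous or missing: the missing
    offspring may be null homozygotes.

    Markers where all, or all but one, F2 are missing are excluded as
    likely assay failures (more than one offspring must have a call).
    """
    mid = marker.id
    calls = [matrix.get(mid, o.id) for o in family.offspring]
    n_missing = sum(1 for c in calls if c is None)
    n_called = len(calls) - n_missing
    if n_missing <= min_missing or n_called <= 1:
        return False
    for par in family.parents:
        pc = matrix.get(mid, par.id)
        if pc is None:
            continue
        if not is_hom(pc):
            return False
        # a called homozygous parent can carry the null only if one of its
        # own parents is called homozygous or missing
        gps = family.grandparents_of(par, roster)
        if gps and not any(
            matrix.get(mid, g.id) is None or is_hom(matrix.get(mid, g.id))
            for g in gps
        ):
            return False
    return True


def _class5_het_absence(matrix: CallMatrix, family: Family, marker: Marker) -> bool:
    """Both homozygotes but no heterozygote among the offspring, one parent
    missing and the other heterozygous: the missing parent may carry two
    null alleles, every offspring inheriting one."""
    mid = marker.id
    p_calls = [matrix.get(mid, p.id) for p in family.parents]
    if not (
        (p_calls[0] is None and is_het(p_calls[1]))
        or (p_calls[1] is None and is_het(p_calls[0]))
    ):
        return False
    counts = {(1, 1): 0, (2, 2): 0, (1, 2): 0}
    for off in family.offspring:
        c = matrix.get(mid, off.id)
        if c is not None:
            counts[c] += 1
    return counts[(1, 2)] == 0 and counts[(1, 1)] > 1 and counts[(2, 2)] > 1


def classify_family(
    matrix: CallMatrix,
    family: Family,
    marker: Marker,
    roster: dict[str, Individual],
    min_missing: int = 5,
) -> SNPFamilyClassification:
    """Assign one category to a SNP in one family."""
    mid = marker.id
    incompats = find_incompatibilities(matrix, family, marker, roster)
    hypotheses = null_consistent(matrix, family, marker, roster)
    missing_f2 = frozenset(
        o.id for o in family.offspring if matrix.get(mid, o.id) is None
    )

    def result(category: str) -> SNPFamilyClassification:
        return SNPFamilyClassification(
            marker_id=mid,
            family_label=family.label,
            category=category,
            hypotheses=hypotheses,
            incompatibilities=incompats,
            n_missing_f2=len(missing_f2),
            missing_f2=missing_f2,
        )

    if incompats:
        if not hypotheses:
            if any(i.kind == "different_homozygotes" for i in incompats):
                return result("err_diffhom")
            return result("err_other")
        if len(incompats) > 1:
            n_edits = min_error_explanation(matrix, family, marker, roster, cap=2)
            return result("class2" if n_edits == 1 else "class1")
        inc = incompats[0]
        p1, p2 = (matrix.get(mid, p.id) for p in family.parents)
        if inc.level == "F0-F1" and is_hom(p1) and p1 == p2:
            return result("class3")
        return result("class4")

    if _class5_missing_pattern(
        matrix, family, marker, roster, min_missing
    ) or _class5_het_absence(matrix, family, marker):
        return result("class5")
    return result("consistent")


def integrate_pair(cat_a: str, cat_b: str) -> str:
    """Overall category for a SNP classified in two families."""
    if cat_a == cat_b:
        return cat_a
    a_null, b_null = cat_a in NULL_CLASSES, cat_b in NULL_CLASSES
    if a_null and b_null:
        pair = {cat_a, cat_b}
        # class 4 is the least reliable: paired with class 5 it yields 5,
        # otherwise the numerically lower class wins
        if pair == {"class4", "class5"}:
            return "class5"
        return min(cat_a, cat_b)  # lexicographic == numeric for classN
    if a_null:
        return cat_a
    if b_null:
        return cat_b
    a_err, b_err = cat_a in ERROR_CATEGORIES, cat_b in ERROR_CATEGORIES
    if a_err and b_err:
        # different homozygotes seen in one family but not the other
        return "err_diffhom"
    if a_err:
        return cat_a
    if b_err:
        return cat_b
    return "consistent"


def integrate_families(
    a: SNPFamilyClassification, b: SNPFamilyClassification
) -> IntegratedClassification:
    """Merge the two families' classifications of one SNP."""
    if a.marker_id != b.marker_id:
        raise ValueError(
            f"cannot integrate different markers: {a.marker_id!r} vs {b.marker_id!r}"
        )
    return IntegratedClassification(
        marker_id=a.marker_id,
        category=integrate_pair(a.category, b.category),
        per_family=[a, b],
        both_families=a.is_null_class and b.is_null_class,
    )


def classify_all(
    matrix: CallMatrix,
    families: list[Family],
    roster: dict[str, Individual],
    min_missing: int = 5,
) -> list[IntegratedClassification]:
    """One integrated classification per marker across all families."""
    out: list[IntegratedClassification] = []
    for marker in matrix.markers:
        per_family = [
            classify_family(matrix, fam, marker, roster, min_missing=min_missing)
            for fam in families
        ]
        if len(per_family) == 1:
            fc = per_family[0]
            out.append(
                IntegratedClassification(
                    marker_id=marker.id,
                    category=fc.category,
                    per_family=per_family,
                    both_families=False,
                )
            )
            continue
        category = per_family[0].category
        for fc in per_family[1:]:
            category = integrate_pair(category, fc.category)
        out.append(
            IntegratedClassification(
                marker_id=marker.id,
                category=category,
                per_family=per_family,
                both_families=sum(fc.is_null_class for fc in per_family) >= 2,
            )
        )
    return out
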
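"""Category assignment for the five null-allele classes, the error
categories, and the two-family integration rules."""

import itertools
import random

import pytest

from pednull import (
    CATEGORIES,
    ERROR_CATEGORIES,
    NULL_CLASSES,
    NullInjection,
    SimConfig,
    classify_all,
    classify_family,
    expected_more_incompatibilities,
    integrate_families,
    min_error_explanation,
    simulate,
)
from pednull.classify import SNPFamilyClassification, integrate_pair
from conftest import GENOTYPES, make_matrix


@pytest.fixture
def fam(family_pedigree):
    return family_pedigree.families[0]


@pytest.fixture
def roster(family_pedigree):
    return family_pedigree.individuals


def build(fam, parents, offspring, f0):
    calls = dict(f0)
    calls[fam.parents[0].id] = parents[0]
    calls[fam.parents[1].id] = parents[1]
    for off, c in zip(fam.offspring, offspring):
        calls[off.id] = c
    return calls


# Each case mirrors one of the canonical single-family configurations:
# (parent calls, offspring calls (padded with the last entry), F0 calls,
# expected category)
CASES = {
    "class1_null_in_both_parents": (
        [(1, 1), (2, 2)],
        [(1, 1)] * 7 + [(2, 2)] * 7,
        {"GF": None, "GM1": (1, 1), "GM2": (2, 2)},
        "class1",
    ),
    "class2_one_error_would_explain": (
        [(1, 1), (2, 2)],
        [(1, 2)] * 8 + [(2, 2)] * 6,
        {"GF": (1, 2), "GM1": None, "GM2": (2, 2)},
        "class2",
    ),
    "class3_grandparent_conflict_only": (
        [(1, 1), (1, 1)],
        [(1, 1)] * 14,
        {"GF": (1, 1), "GM1": (1, 1), "GM2": (2, 2)},
        "class3",
    ),
    "class4_single_f2_conflict": (
        [(1, 1), (1, 2)],
        [(2, 2)] + [(1, 1), (1, 2)] * 6 + [(1, 1)],
        {"GF": (1, 2), "GM1": None, "GM2": (1, 2)},
        "class4",
    ),
    "class5_many_missing": (
        [(1, 1), (1, 1)],
        [None] * 8 + [(1, 1)] * 6,
        {"GF": (1, 1), "GM1": None, "GM2": None},
        "class5",
    ),
    "class5_het_absence": (
        [None, (1, 2)],
        [(1, 1)] * 6 + [(2, 2)] * 8,
        {"GF": (1, 2), "GM1": None, "GM2": (1, 2)},
        "class5",
    ),
    "err_diffhom_no_null_possible": (
        [(1, 1), (1, 1)],
        [(2, 2)] + [(1, 1)] * 13,
        {"GF": (1, 2), "GM1": (1, 2), "GM2": (1, 2)},
        "err_diffhom",
    ),
    "err_other_unexplained_het": (
        [(1, 1), (1, 1)],
        [(1, 2)] + [(1, 1)] * 13,
        {"GF": (1, 2), "GM1": (1, 2), "GM2": (1, 2)},
        "err_other",
    ),
    "consistent": (
        [(1, 1), (1, 2)],
        [(1, 1), (1, 2)] * 7,
        {"GF": (1, 2), "GM1": (1, 2), "GM2": (1, 2)},
        "consistent",
    ),
}


@pytest.mark.parametrize("name", CASES)
def test_category_assignment(name, fam, roster, marker):
    parents, offspring, f0, expected = CASES[name]
    mat = make_matrix(marker, build(fam, parents, offspring, f0))
    fc = classify_family(mat, fam, marker, roster)
    assert fc.category == expected


class TestClass5Rules:
    def test_min_missing_is_strict_threshold(self, fam, roster, marker):
        """Exactly min_missing missing F2 is not enough; one more is."""
        f0 = {"GF": (1, 1), "GM1": None, "GM2": None}
        for n_miss, expected in [(5, "consistent"), (6, "class5")]:
            offspring = [None] * n_miss + [(1, 1)] * (14 - n_miss)
            mat = make_matrix(marker, build(fam, [(1, 1), (1, 1)], offspring, f0))
            assert classify_family(mat, fam, marker, roster).category == expected

    def test_min_missing_knob(self, fam, roster, marker):
        f0 = {"GF": (1, 1), "GM1": None, "GM2": None}
        offspring = [None] * 4 + [(1, 1)] * 10
        mat = make_matrix(marker, build(fam, [(1, 1), (1, 1)], offspring, f0))
        assert classify_family(mat, fam, marker, roster).category == "consistent"
        assert (
            classify_family(mat, fam, marker, roster, min_missing=3).category
            == "class5"
        )

    def test_assay_failure_filter(self, fam, roster, marker):
        """All, or all but one, F2 missing is excluded (likely assay
        failure, not a null allele)."""
        f0 = {"GF": (1, 1), "GM1": None, "GM2": None}
        for n_called in (0, 1):
            offspring = [(1, 1)] * n_called + [None] * (14 - n_called)
            mat = make_matrix(marker, build(fam, [(1, 1), (1, 1)], offspring, f0))
            assert classify_family(mat, fam, marker, roster).category == "consistent"
        offspring = [(1, 1)] * 2 + [None] * 12
        mat = make_matrix(marker, build(fam, [(1, 1), (1, 1)], offspring, f0))
        assert classify_family(mat, fam, marker, roster).category == "class5"

    def test_het_absence_requires_both_homozygotes_twice(self, fam, roster, marker):
        f0 = {"GF": (1, 2), "GM1": None, "GM2": (1, 2)}
        offspring = [(1, 1)] * 13 + [(2, 2)]  # only one (2,2)
        mat = make_matrix(marker, build(fam, [None, (1, 2)], offspring, f0))
        assert classify_family(mat, fam, marker, roster).category == "consistent"


class TestExpectedMore:
    def make_hyp(self, fam, roster, marker, parents, offspring, f0):
        from pednull import null_consistent

        mat = make_matrix(marker, build(fam, parents, offspring, f0))
        hyps = null_consistent(mat, fam, marker, roster)
        assert hyps
        return mat, hyps

    def test_het_coparent_true(self, fam, roster, marker):
        mat, hyps = self.make_hyp(
            fam,
            roster,
            marker,
            [(1, 1), (1, 2)],
            [(2, 2)] + [(1, 1), (1, 2)] * 6 + [(1, 1)],
            {"GF": (1, 2), "GM1": None, "GM2": (1, 2)},
        )
        assert any(
            expected_more_incompatibilities(h, fam, marker, mat) for h in hyps
        )

    def test_same_homozygote_coparent_false(self, fam, roster, marker):
        mat, hyps = self.make_hyp(
            fam,
            roster,
            marker,
            [(1, 1), (1, 1)],
            [(1, 1)] * 14,
            {"GF": (1, 1), "GM1": (1, 1), "GM2": (2, 2)},
        )
        assert all(
            not expected_more_incompatibilities(h, fam, marker, mat) for h in hyps
        )

    def test_opposite_homozygote_coparent_true(self, fam, roster, marker):
        mat, hyps = self.make_hyp(
            fam,
            roster,
            marker,
            [(1, 1), (2, 2)],
            [(1, 2)] * 8 + [(2, 2)] * 6,
            {"GF": (1, 2), "GM1": None, "GM2": (2, 2)},
        )
        assert all(expected_more_incompatibilities(h, fam, marker, mat) for h in hyps)


def fc(category, marker_id="rs1", family="1"):
    return SNPFamilyClassification(
        marker_id=marker_id, family_label=family, category=category
    )


class TestIntegration:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("class2", "class4", "class2"),  # numerically lower class
            ("class1", "class3", "class1"),
            ("class4", "class5", "class5"),  # class 4 defers to class 5
            ("class2", "class5", "class2"),
            ("err_other", "err_diffhom", "err_diffhom"),
            ("class3", "err_diffhom", "class3"),  # null evidence wins
            ("class5", "consistent", "class5"),
            ("err_other", "consistent", "err_other"),
            ("consistent", "consistent", "consistent"),
        ],
    )
    def test_rules(self, a, b, expected):
        ic = integrate_families(fc(a, family="1"), fc(b, family="2"))
        assert ic.category == expected

    def test_symmetry(self):
        for a, b in itertools.product(CATEGORIES, repeat=2):
            assert integrate_pair(a, b) == integrate_pair(b, a)

    def test_both_families_flag(self):
        assert integrate_families(fc("class5"), fc("class2", family="2")).both_families
        assert not integrate_families(
            fc("class5"), fc("consistent", family="2")
        ).both_families
        assert not integrate_families(
            fc("err_diffhom"), fc("err_diffhom", family="2")
        ).both_families

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValueError):
            integrate_families(fc("class1", "rs1"), fc("class1", "rs2"))


class TestFuzzInvariants:
    def test_exclusive_exhaustive_and_cross_checks(self, fam, roster, marker):
        """Random single-marker matrices always land in exactly one valid
        category, and the category's defining conditions hold."""
        rng = random.Random(123)
        members = fam.members(roster)
        seen = set()
        for _ in range(300):
            calls = {
                m.id: (None if rng.random() < 0.25 else GENOTYPES[rng.randrange(3)])
                for m in members
            }
            mat = make_matrix(marker, calls)
            fcr = classify_family(mat, fam, marker, roster)
            assert fcr.category in CATEGORIES
            seen.add(fcr.category)
            if fcr.category in ERROR_CATEGORIES:
                assert fcr.hypotheses == []
                assert fcr.n_incompatibilities >= 1
            if fcr.category in ("class1", "class2", "class3", "class4"):
                assert fcr.hypotheses
            if fcr.category == "class1":
                assert min_error_explanation(mat, fam, marker, roster, cap=2) >= 2
            if fcr.category == "class2":
                assert min_error_explanation(mat, fam, marker, roster, cap=2) == 1
        assert "consistent" in seen  # fuzz actually explored the easy region


class TestClassifyAll:
    def test_clean_simulation_all_consistent(self):
        mat, ped, _ = simulate(SimConfig(n_markers=40, seed=5))
        res = classify_all(mat, ped.families, ped.individuals)
        assert all(ic.category == "consistent" for ic in res)

    def test_injected_homozygous_null_is_class5_in_both_families(self):
        """A grandfather homozygous for a null at one marker: many F2 in
        each family lose their calls, giving class 5 with two-family
        support (seed chosen so the segregation realizes the pattern)."""
        inj = (NullInjection("GF", 2, 1, 0), NullInjection("GF", 2, 1, 1))
        cfg = SimConfig(
            n_markers=5, seed=2, founder_allele_freq=1.0, null_injections=inj
        )
        mat, ped, truth = simulate(cfg)
        assert truth.mechanism["snp00003"] == "null"
        res = classify_all(mat, ped.families, ped.individuals)
        by_id = {ic.marker_id: ic for ic in res}
        assert by_id["snp00003"].category == "class5"
        assert by_id["snp00003"].both_families
        for mid in ("snp00001", "snp00002", "snp00004", "snp00005"):
            assert by_id[mid].category == "consistent"

    def test_null_recall_on_simulated_truth(self):
        """Across seeded replicates, single-marker nulls injected into the
        grandfather are recovered as null classes whenever their
        transmission produces a detectable pattern; detected markers are
        never mislabeled as errors."""
        n_detectable = n_recovered = 0
        for seed in range(15):
            cfg = SimConfig(
                n_markers=8,
                seed=seed,
                null_injections=(NullInjection("GF", 3),),
            )
            mat, ped, truth = simulate(cfg)
            res = classify_all(mat, ped.families, ped.individuals)
            ic = next(r for r in res if r.marker_id == "snp00004")
            assert ic.category not in ERROR_CATEGORIES
            if ic.category != "consistent":
                n_recovered += 1
            # detectable = some family shows an incompatibility or a
            # missing double-null offspring
            for fc_ in ic.per_family:
                if fc_.n_incompatibilities or fc_.category != "consistent":
                    n_detectable += 1
                    break
        assert n_recovered == n_detectable > 0
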
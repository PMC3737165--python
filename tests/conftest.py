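"""Shared fixtures: a small three-generation family and matrix builders."""

import itertools

import pytest

from pednull import CallMatrix, Marker, build_pedigree

GENOTYPES = [(1, 1), (1, 2), (2, 2)]


@pytest.fixture
def marker():
    return Marker("rs1", "1", 1000)


@pytest.fixture
def small_pedigree():
    """One family: GF, GM1, GM2 grandparents, two F1, three F2."""
    return build_pedigree((3,))


@pytest.fixture
def family_pedigree():
    """One family of 14 F2 (enough for class-5 missing patterns)."""
    return build_pedigree((14,))


def make_matrix(marker, calls):
    """CallMatrix over one marker from an {individual: call} dict."""
    mat = CallMatrix(markers=[marker], individuals=list(calls))
    for ind, call in calls.items():
        mat.set(marker.id, ind, call)
    return mat


# ---------------------------------------------------------------------------
# Independent Mendelian oracles (enumeration-based, no shared code with the
# implementation's consistency machinery)
# ---------------------------------------------------------------------------


def mendelian_child_ok(child, p1, p2):
    """Child genotype composable as one allele from each parent genotype."""
    return any(
        tuple(sorted((a, b))) == child for a in p1 for b in p2
    )


def oracle_consistent(calls, members):
    """Exhaustive check: some assignment of genotypes to missing members
    makes every parent-offspring trio Mendelian."""
    missing = [m.id for m in members if calls.get(m.id) is None]
    linked = [m for m in members if m.sire is not None]
    for combo in itertools.product(GENOTYPES, repeat=len(missing)):
        g = dict(calls)
        g.update(zip(missing, combo))
        if all(
            mendelian_child_ok(g[m.id], g[m.sire], g[m.dam])
            for m in linked
            if m.sire in g and m.dam in g
        ):
            return True
    return False


def oracle_min_edits(calls, members, cap=2):
    """Breadth-first brute-force edit search against oracle_consistent."""
    if oracle_consistent(calls, members):
        return 0
    edits = [
        (m.id, g)
        for m in members
        if calls.get(m.id) is not None
        for g in GENOTYPES
        if g != calls[m.id]
    ]
    for depth in range(1, cap):
        for combo in itertools.combinations(edits, depth):
            if len({e[0] for e in combo}) != depth:
                continue
            trial = dict(calls)
            for ind_id, g in combo:
                trial[ind_id] = g
            if oracle_consistent(trial, members):
                return depth
    return cap
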
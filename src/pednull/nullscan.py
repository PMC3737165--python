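"""Mendelian incompatibility detection and null-allele consistency checks.

A null allele is a marker allele that fails to amplify: an individual
heterozygous for a null is called homozygous for its visible allele, and a
null homozygote yields a missing call. This module decides, per SNP per
family, (a) which parent-offspring genotype pairs are Mendelian-impossible,
(b) whether the full three-generation genotype configuration can be
explained by null alleles carried by the F1 parents, and (c) how many
single-genotype substitutions would instead be needed to restore Mendelian
consistency without invoking nulls.

True genotypes are modelled as unordered pairs over {1, 2, 0} where 0 is
the null allele; the observation model is

    (a, b) -> (a, b)        both alleles amplify
    (a, 0) -> (a, a)        hemizygous carrier called homozygous
    (0, 0) -> missing       null homozygote fails entirely
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

from .pedmodel import (
    Call,
    CallMatrix,
    Family,
    GENOTYPES,
    Individual,
    Marker,
    is_hom,
)

NULL = 0

@dataclass(frozen=True)
class Incompatibility:
    """One Mendelian violation between one parent and one offspring.

    ``kind`` is ``different_homozygotes`` when the pair are called
    homozygous for different alleles — the only way a single parent-offspring
    pair can conflict at a biallelic marker — and ``other`` for violations
    that only appear when the offspring is checked against both parents
    jointly (e.g. a heterozygous offspring of two identical homozygotes);
    those are attributed to the first parent of the pair.
    """

    marker_id: str
    parent_id: str
    offspring_id: str
    level: str  # "F1-F2" | "F0-F1"
    kind: str  # "different_homozygotes" | "other"


@dataclass(frozen=True)
class NullHypothesis:
    """An assignment of null alleles to F1 parents explaining the calls.

    ``carriers`` maps each carrier parent id to its hypothesised true
    genotype (visible allele paired with 0, or (0, 0)). ``f2_carriers``
    are offspring whose observed calls require a transmitted null under
    this assignment (missing offspring are included when the hypothesis
    makes them null homozygotes). ``sources`` records, per carrier parent,
    the F0 grandparent the null can be traced to, or None when unresolved.
    """

    marker_id: str
    carriers: tuple[tuple[str, tuple[int, int]], ...]
    f2_carriers: frozenset[str]
    sources: tuple[tuple[str, Optional[str]], ...]

    @property
    def carrier_parent_ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.carriers)


def _allele_set(call: Call) -> set[int]:
    """Alleles a called individual can transmit; missing transmits anything."""
    if call is None:
        return {1, 2}
    return set(call)


def _pair_diffhom(parent: Call, child: Call) -> bool:
    return (
        is_hom(parent) and is_hom(child) and parent[0] != child[0]
    )


def _trio_possible(child: Call, p1: Call, p2: Call) -> bool:
    """Can ``child`` be formed from one allele of each parent's call?"""
    if child is None:
        return True
    a, b = child
    s1, s2 = _allele_set(p1), _allele_set(p2)
    return (a in s1 and b in s2) or (b in s1 and a in s2)


def find_incompatibilities(
    matrix: CallMatrix, family: Family, marker: Marker, roster: dict[str, Individual]
) -> list[Incompatibility]:
    """All Mendelian violations at ``marker`` in ``family``.

    Checks every F1-F2 and F0-F1 parent-offspring pair; missing calls never
    generate incompatibilities. One offspring conflicting with both parents
    counts twice (the counting unit is the pair).
    """
    mid = marker.id
    out: list[Incompatibility] = []

    def check(child: Individual, p1: Individual, p2: Individual, level: str) -> None:
        c = matrix.get(mid, child.id)
        if c is None:
            return
        g1, g2 = matrix.get(mid, p1.id), matrix.get(mid, p2.id)
        pairwise = False
        for par, g in ((p1, g1), (p2, g2)):
            if _pair_diffhom(g, c):
                out.append(Incompatibility(mid, par.id, child.id, level, "different_homozygotes"))
                pairwise = True
        if not pairwise and not _trio_possible(c, g1, g2):
            out.append(Incompatibility(mid, p1.id, child.id, level, "other"))

    par1, par2 = family.parents
    for par in family.parents:
        gps = family.grandparents_of(par, roster)
        if len(gps) == 2:
            check(par, gps[0], gps[1], "F0-F1")
    for off in family.offspring:
        check(off, par1, par2, "F1-F2")
    return out


# ---------------------------------------------------------------------------
# Null-allele hypothesis enumeration
# ---------------------------------------------------------------------------


def _observe(true_g: tuple[int, int]) -> Call:
    a, b = true_g
    if a == NULL and b == NULL:
        return None
    if b == NULL:
        return (a, a)
    if a == NULL:
        return (b, b)
    return (a, b) if a <= b else (b, a)


def _parent_true_options(call: Call, n_nulls: int) -> list[tuple[int, int]]:
    """True genotypes for an F1 parent carrying ``n_nulls``, given its call."""
    if n_nulls == 0:
        if call is None:
            return [(1, 1), (1, 2), (2, 2)]
        return [call]
    if n_nulls == 1:
        if call is None:
            return [(1, NULL), (2, NULL)]
        if is_hom(call):
            return [(call[0], NULL)]
        return []  # an observed heterozygote has both alleles amplifying
    # two nulls: the parent cannot yield a call at all
    return [(NULL, NULL)] if call is None else []


def _canon(a: int, b: int) -> tuple[int, int]:
    """Canonical true-genotype form: alleles ascending, nulls last."""
    if a == NULL or b == NULL:
        return (max(a, b), min(a, b))
    return (a, b) if a <= b else (b, a)


def _compose(t1: tuple[int, int], t2: tuple[int, int]) -> set[tuple[int, int]]:
    """All true offspring genotypes from one allele of each parent genotype."""
    return {_canon(a, b) for a in t1 for b in t2}


def _grandparent_filter(
    matrix: CallMatrix,
    marker_id: str,
    parent: Individual,
    roster: dict[str, Individual],
    family: Family,
) -> bool:
    """For an F1 to carry a null, one of its F0 parents must be called
    homozygous or missing."""
    gps = family.grandparents_of(parent, roster)
    if not gps:
        return False
    return any(
        matrix.get(marker_id, g.id) is None or is_hom(matrix.get(marker_id, g.id))
        for g in gps
    )


def _f0_true_options(call: Call, may_carry_null: bool) -> list[tuple[int, int]]:
    opts: list[tuple[int, int]] = []
    if call is None:
        opts = [(1, 1), (1, 2), (2, 2)]
        if may_carry_null:
            opts += [(1, NULL), (2, NULL), (NULL, NULL)]
    elif is_hom(call):
        opts = [call]
        if may_carry_null:
            opts.append((call[0], NULL))
    else:
        opts = [call]
    return opts


def _f0_layer_consistent(
    matrix: CallMatrix,
    marker_id: str,
    family: Family,
    roster: dict[str, Individual],
    parent_true: dict[str, tuple[int, int]],
    null_ok_f0: set[str],
) -> bool:
    """Check the F1 true genotypes are derivable from the F0 generation.

    ``null_ok_f0`` lists the F0 individuals permitted to carry a null (the
    designated grandparental sources). Distinct F0 individuals (the
    grandfather is shared between the two F1 parents) get one joint true
    genotype.
    """
    f0_ids: list[str] = []
    for par in family.parents:
        for g in family.grandparents_of(par, roster):
            if g.id not in f0_ids:
                f0_ids.append(g.id)
    domains = [
        _f0_true_options(matrix.get(marker_id, gid), gid in null_ok_f0)
        for gid in f0_ids
    ]
    for combo in itertools.product(*domains):
        assign = dict(zip(f0_ids, combo))
        ok = True
        for par in family.parents:
            gps = family.grandparents_of(par, roster)
            if len(gps) != 2:
                ok = False
                break
            if parent_true[par.id] not in _compose(assign[gps[0].id], assign[gps[1].id]):
                ok = False
                break
        if ok:
            return True
    return False


def null_consistent(
    matrix: CallMatrix, family: Family, marker: Marker, roster: dict[str, Individual]
) -> list[NullHypothesis]:
    """Enumerate null-allele assignments to the F1 parents that explain the
    observed calls across all three generations.

    A hypothesis must (a) reproduce every non-missing call when read through
    the observation model, (b) pass the grandparent filter for each carrier,
    and (c) be derivable from some F0 true-genotype assignment. An empty
    list means the marker is not explainable by nulls alone (or shows no
    evidence calling for a null at all).
    """
    mid = marker.id
    par1, par2 = family.parents
    incompats = find_incompatibilities(matrix, family, marker, roster)
    any_missing = any(
        matrix.get(mid, ind.id) is None
        for ind in (par1, par2, *family.offspring)
    )
    if not incompats and not any_missing:
        return []

    hypotheses: list[NullHypothesis] = []
    seen: set[tuple] = set()
    for n1, n2 in itertools.product((0, 1, 2), repeat=2):
        if n1 == 0 and n2 == 0:
            continue
        opts1 = _parent_true_options(matrix.get(mid, par1.id), n1)
        opts2 = _parent_true_options(matrix.get(mid, par2.id), n2)
        for t1, t2 in itertools.product(opts1, opts2):
            hyp = _check_assignment(
                matrix, family, marker, roster, {par1.id: t1, par2.id: t2}
            )
            if hyp is not None:
                key = (hyp.carriers, hyp.f2_carriers)
                if key not in seen:
                    seen.add(key)
                    hypotheses.append(hyp)
    return hypotheses


def _check_assignment(
    matrix: CallMatrix,
    family: Family,
    marker: Marker,
    roster: dict[str, Individual],
    parent_true: dict[str, tuple[int, int]],
) -> Optional[NullHypothesis]:
    mid = marker.id
    carriers = {pid: t for pid, t in parent_true.items() if NULL in t}
    # grandparent filter for every carrier
    for par in family.parents:
        if par.id in carriers and not _grandparent_filter(matrix, mid, par, roster, family):
            return None
    # offspring layer: every called offspring must be producible; track which
    # offspring require a transmitted null
    t1 = parent_true[family.parents[0].id]
    t2 = parent_true[family.parents[1].id]
    possible = _compose(t1, t2)
    f2_carriers: set[str] = set()
    for off in family.offspring:
        call = matrix.get(mid, off.id)
        if call is None:
            if (NULL, NULL) in possible:
                f2_carriers.add(off.id)
            continue
        matches = [g for g in possible if _observe(g) == call]
        if not matches:
            return None
        if all(NULL in g for g in matches):
            f2_carriers.add(off.id)
    # F0 layer: try each designation of a grandparental source per carrier.
    # A one-null carrier traces its null to a single F0 parent; a two-null
    # carrier needs a null from each (recorded with source None = both).
    source_choices: list[list[tuple[str, Optional[str], frozenset[str]]]] = []
    for par in family.parents:
        if par.id not in carriers:
            continue
        gps = family.grandparents_of(par, roster)
        n_nulls = sum(1 for a in carriers[par.id] if a == NULL)
        if n_nulls == 2:
            source_choices.append(
                [(par.id, None, frozenset(g.id for g in gps))]
            )
        else:
            source_choices.append(
                [(par.id, g.id, frozenset({g.id})) for g in gps]
            )
    for combo in itertools.product(*source_choices):
        null_ok: set[str] = set()
        resolved: dict[str, Optional[str]] = {}
        for pid, src, allowed in combo:
            resolved[pid] = src
            null_ok |= allowed
        if _f0_layer_consistent(matrix, mid, family, roster, parent_true, null_ok):
            return NullHypothesis(
                marker_id=mid,
                carriers=tuple(sorted(carriers.items())),
                f2_carriers=frozenset(f2_carriers),
                sources=tuple(sorted(resolved.items())),
            )
    return None


# ---------------------------------------------------------------------------
# Minimum genotyping-error explanation
# ---------------------------------------------------------------------------


def _family_consistent(
    calls: dict[str, Call], family: Family, roster: dict[str, Individual]
) -> bool:
    """Is there a Mendelian-consistent, null-free assignment of true
    genotypes matching all non-missing calls (missing = unconstrained)?

    The two F1 parents may share F0 individuals, so the F0/F1 layer is
    solved jointly; offspring are then independent given the F1 pair.
    """
    par1, par2 = family.parents
    f0_ids: list[str] = []
    for par in family.parents:
        for g in family.grandparents_of(par, roster):
            if g.id not in f0_ids:
                f0_ids.append(g.id)

    def domain(ind_id: str) -> list[tuple[int, int]]:
        c = calls.get(ind_id)
        return list(GENOTYPES) if c is None else [c]

    off_calls = [calls.get(o.id) for o in family.offspring]
    for combo in itertools.product(domain(par1.id), domain(par2.id)):
        g1, g2 = combo
        if not all(_trio_possible(c, g1, g2) for c in off_calls):
            continue
        # F0 layer jointly
        found = False
        for f0_combo in itertools.product(*(domain(g) for g in f0_ids)):
            assign = dict(zip(f0_ids, f0_combo))
            ok = True
            for par, g in ((par1, g1), (par2, g2)):
                gps = family.grandparents_of(par, roster)
                if len(gps) != 2:
                    ok = False
                    break
                if g not in _compose(assign[gps[0].id], assign[gps[1].id]):
                    ok = False
                    break
            if ok:
                found = True
                break
        if found:
            return True
    return False


def min_error_explanation(
    matrix: CallMatrix,
    family: Family,
    marker: Marker,
    roster: dict[str, Individual],
    cap: int = 3,
) -> int:
    """Minimum number of single-genotype substitutions restoring Mendelian
    consistency without nulls, breadth-first in edit count.

    Replacements are concrete genotypes (never missing); any family member
    including the F0 grandparents may be edited. Returns ``cap`` when no
    explanation with fewer than ``cap`` edits exists (downstream logic only
    distinguishes 0 / 1 / >=2).
    """
    mid = marker.id
    members = family.members(roster)
    calls: dict[str, Call] = {m.id: matrix.get(mid, m.id) for m in members}
    if _family_consistent(calls, family, roster):
        return 0
    edits: list[tuple[str, tuple[int, int]]] = [
        (m.id, g)
        for m in members
        if calls[m.id] is not None
        for g in GENOTYPES
        if g != calls[m.id]
    ]
    for depth in range(1, cap):
        for combo in itertools.combinations(edits, depth):
            ids = [e[0] for e in combo]
            if len(set(ids)) != depth:
                continue
            trial = dict(calls)
            for ind_id, g in combo:
                trial[ind_id] = g
            if _family_consistent(trial, family, roster):
                return depth
    return cap
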
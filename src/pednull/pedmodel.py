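"""Data model for markers, pedigrees, and genotype calls.

Genotype calls at biallelic SNPs are represented as sorted ``(a, b)``
tuples with allele codes in ``{1, 2}``, or ``None`` for a missing call.
A half-missing call (one allele coded ``0``) is treated as fully missing:
the downstream null-allele model has no notion of half-calls, matching the
``--`` missing convention of array genotype exports.

Supported on-disk formats:

* PED/MAP (PLINK text dialect): PED rows are ``<individual id>`` followed
  by two whitespace-separated allele columns per marker, in map order;
  ``0 0`` encodes a missing call. MAP rows are ``<chrom> <id> <position>``.
* Long-format genotype TSV with columns ``marker individual allele1 allele2``.
* Pedigree TSV with columns ``individual sire dam generation families``
  (``families`` is a comma-separated list of family labels; ``0`` or an
  empty field means no recorded parent / no family membership).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

#: A genotype call: sorted allele pair, or None when missing.
Call = Optional[tuple[int, int]]

MISSING: Call = None

GENOTYPES: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (2, 2))


class FormatError(ValueError):
    """Raised for malformed genotype or map input."""


class PedigreeError(ValueError):
    """Raised for an inconsistent pedigree structure."""


def make_call(a: int, b: int) -> Call:
    """Build a call from two allele codes; 0 in either position means missing."""
    if a not in (0, 1, 2) or b not in (0, 1, 2):
        raise FormatError(f"allele code outside {{0,1,2}}: {a} {b}")
    if a == 0 or b == 0:
        return MISSING
    return (a, b) if a <= b else (b, a)


def is_hom(call: Call) -> bool:
    return call is not None and call[0] == call[1]


def is_het(call: Call) -> bool:
    return call is not None and call[0] != call[1]


def call_str(call: Call) -> str:
    return "--" if call is None else f"{call[0]}{call[1]}"


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with a physical position (1-based bp)."""

    id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"marker {self.id}: position must be >= 1")


@dataclass
class Individual:
    id: str
    generation: str  # "F0" | "F1" | "F2"
    sire: Optional[str] = None
    dam: Optional[str] = None


@dataclass
class Family:
    """A three-generation family: two F1 parents and their F2 offspring.

    Families may share individuals (the intercross design has one F0
    grandfather common to all F1 parents); shared individuals are stored
    once in the pedigree roster and referenced from each family.
    """

    label: str
    parents: tuple[Individual, Individual]
    offspring: list[Individual]

    def members(self, roster: dict[str, Individual]) -> list[Individual]:
        """All distinct family members: F0 grandparents, parents, offspring."""
        seen: dict[str, Individual] = {}
        for par in self.parents:
            for gp_id in (par.sire, par.dam):
                if gp_id is not None and gp_id not in seen:
                    seen[gp_id] = roster[gp_id]
        for par in self.parents:
            seen.setdefault(par.id, par)
        for off in self.offspring:
            seen.setdefault(off.id, off)
        return list(seen.values())

    def grandparents_of(
        self, parent: Individual, roster: dict[str, Individual]
    ) -> list[Individual]:
        return [roster[g] for g in (parent.sire, parent.dam) if g is not None]


@dataclass
class Pedigree:
    individuals: dict[str, Individual]
    families: list[Family]


@dataclass
class CallMatrix:
    """Genotype calls addressable by (marker id, individual id).

    Only non-missing calls are stored; lookups of absent pairs return the
    missing call, so any (marker, individual) combination is addressable.
    """

    markers: list[Marker]
    individuals: list[str]
    calls: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def get(self, marker_id: str, individual_id: str) -> Call:
        return self.calls.get((marker_id, individual_id))

    def set(self, marker_id: str, individual_id: str, call: Call) -> None:
        key = (marker_id, individual_id)
        if call is None:
            self.calls.pop(key, None)
        else:
            self.calls[key] = call

    def marker_by_id(self, marker_id: str) -> Marker:
        for m in self.markers:
            if m.id == marker_id:
                return m
        raise KeyError(marker_id)

    def sorted_markers(self) -> list[Marker]:
        return sorted(self.markers, key=lambda m: (m.chromosome, m.position))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallMatrix):
            return NotImplemented
        return (
            self.markers == other.markers
            and sorted(self.individuals) == sorted(other.individuals)
            and self.calls == other.calls
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_map(map_path: str | Path) -> list[Marker]:
    markers: list[Marker] = []
    seen: set[str] = set()
    for lineno, line in enumerate(_lines(map_path), start=1):
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(
                f"{map_path}:{lineno}: expected 3 columns (chrom id position), "
                f"got {len(parts)}"
            )
        chrom, mid, pos = parts
        if mid in seen:
            raise FormatError(f"{map_path}:{lineno}: duplicate marker id {mid!r}")
        seen.add(mid)
        try:
            markers.append(Marker(id=mid, chromosome=chrom, position=int(pos)))
        except ValueError as exc:
            raise FormatError(f"{map_path}:{lineno}: {exc}") from exc
    return markers


def read_genotypes(ped_path: str | Path, map_path: str | Path) -> CallMatrix:
    """Read a PED/MAP pair into a CallMatrix.

    PED rows carry the individual id followed by two allele columns per
    marker in map order; ``0`` alleles mark missing calls.
    """
    markers = read_map(map_path)
    matrix = CallMatrix(markers=markers, individuals=[])
    n_alleles = 2 * len(markers)
    for lineno, line in enumerate(_lines(ped_path), start=1):
        parts = line.split()
        if len(parts) != 1 + n_alleles:
            raise FormatError(
                f"{ped_path}:{lineno}: expected {1 + n_alleles} columns for "
                f"{len(markers)} markers, got {len(parts)}"
            )
        ind = parts[0]
        if ind in matrix.individuals:
            raise FormatError(f"{ped_path}:{lineno}: duplicate individual {ind!r}")
        matrix.individuals.append(ind)
        for i, marker in enumerate(markers):
            try:
                a, b = int(parts[1 + 2 * i]), int(parts[2 + 2 * i])
                call = make_call(a, b)
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{ped_path}:{lineno}: {exc}") from exc
            matrix.set(marker.id, ind, call)
    return matrix


def write_genotypes(
    matrix: CallMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a CallMatrix as a PED/MAP pair (round-trips exactly)."""
    with open(map_path, "w") as fh:
        for m in matrix.markers:
            fh.write(f"{m.chromosome}\t{m.id}\t{m.position}\n")
    with open(ped_path, "w") as fh:
        for ind in matrix.individuals:
            fields = [ind]
            for m in matrix.markers:
                call = matrix.get(m.id, ind)
                a, b = (0, 0) if call is None else call
                fields.append(f"{a} {b}")
            fh.write(" ".join(fields) + "\n")


def read_genotypes_long(path: str | Path) -> CallMatrix:
    """Read a long-format genotype TSV (marker, individual, allele1, allele2).

    Produces the same CallMatrix as the PED/MAP reader would on equivalent
    content; marker positions are unknown in this format and default to the
    row-order index (attach a map separately when positions matter).
    """
    marker_order: list[str] = []
    individuals: list[str] = []
    raw: dict[tuple[str, str], Call] = {}
    rows = _lines(path)
    for lineno, line in enumerate(rows, start=1):
        parts = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and parts[:2] == ["marker", "individual"]:
            continue
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        mid, ind, a, b = parts
        try:
            call = make_call(int(a), int(b))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        key = (mid, ind)
        if key in raw:
            if raw[key] != call:
                raise FormatError(
                    f"{path}:{lineno}: conflicting duplicate call for "
                    f"marker {mid!r}, individual {ind!r}"
                )
            continue
        raw[key] = call
        if mid not in marker_order:
            marker_order.append(mid)
        if ind not in individuals:
            individuals.append(ind)
    markers = [
        Marker(id=mid, chromosome="0", position=i + 1)
        for i, mid in enumerate(sorted(marker_order))
    ]
    matrix = CallMatrix(markers=markers, individuals=sorted(individuals))
    for (mid, ind), call in raw.items():
        matrix.set(mid, ind, call)
    return matrix


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree TSV and assemble families.

    Generation labels are validated against the link structure: F2 need F1
    parents, F1 need F0 parents, F0 must be parentless. Each family label
    must select exactly two F1 individuals (the parents).
    """
    roster: dict[str, Individual] = {}
    fam_members: dict[str, list[str]] = {}
    fam_order: list[str] = []
    for lineno, line in enumerate(_lines(path), start=1):
        parts = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and parts and parts[0] == "individual":
            continue
        if len(parts) != 5:
            raise PedigreeError(
                f"{path}:{lineno}: expected 5 columns "
                "(individual sire dam generation families)"
            )
        ind_id, sire, dam, gen, fams = parts
        if gen not in ("F0", "F1", "F2"):
            raise PedigreeError(f"{path}:{lineno}: bad generation {gen!r}")
        if ind_id in roster:
            raise PedigreeError(f"{path}:{lineno}: duplicate individual {ind_id!r}")
        roster[ind_id] = Individual(
            id=ind_id,
            generation=gen,
            sire=None if sire in ("0", "") else sire,
            dam=None if dam in ("0", "") else dam,
        )
        for label in fams.split(","):
            label = label.strip()
            if label in ("", "0"):
                continue
            if label not in fam_members:
                fam_members[label] = []
                fam_order.append(label)
            fam_members[label].append(ind_id)
    _validate_links(roster)
    families = []
    for label in fam_order:
        members = [roster[i] for i in fam_members[label]]
        f1 = [m for m in members if m.generation == "F1"]
        f2 = [m for m in members if m.generation == "F2"]
        if len(f1) != 2:
            raise PedigreeError(
                f"family {label!r}: expected exactly 2 F1 parents, got {len(f1)}"
            )
        for off in f2:
            if {off.sire, off.dam} != {f1[0].id, f1[1].id}:
                raise PedigreeError(
                    f"family {label!r}: offspring {off.id!r} parents "
                    f"({off.sire}, {off.dam}) are not the family's F1 pair"
                )
        families.append(Family(label=label, parents=(f1[0], f1[1]), offspring=f2))
    return Pedigree(individuals=roster, families=families)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    memberships: dict[str, list[str]] = {i: [] for i in pedigree.individuals}
    for fam in pedigree.families:
        for ind in fam.members(pedigree.individuals):
            memberships[ind.id].append(fam.label)
    with open(path, "w") as fh:
        fh.write("individual\tsire\tdam\tgeneration\tfamilies\n")
        for ind in pedigree.individuals.values():
            fams = ",".join(memberships[ind.id]) or "0"
            fh.write(
                f"{ind.id}\t{ind.sire or 0}\t{ind.dam or 0}\t"
                f"{ind.generation}\t{fams}\n"
            )


def _validate_links(roster: dict[str, Individual]) -> None:
    for ind in roster.values():
        if ind.generation == "F0":
            if ind.sire or ind.dam:
                raise PedigreeError(f"F0 individual {ind.id!r} has recorded parents")
            continue
        want = "F0" if ind.generation == "F1" else "F1"
        for role, pid in (("sire", ind.sire), ("dam", ind.dam)):
            if pid is None:
                raise PedigreeError(
                    f"{ind.generation} individual {ind.id!r} is missing a {role} "
                    f"({want} record required)"
                )
            if pid not in roster:
                raise PedigreeError(
                    f"individual {ind.id!r}: {role} {pid!r} not in pedigree"
                )
            if roster[pid].generation != want:
                raise PedigreeError(
                    f"individual {ind.id!r}: {role} {pid!r} is "
                    f"{roster[pid].generation}, expected {want}"
                )
    # generation checks force parent links strictly down the F2->F1->F0
    # hierarchy, so parentage is necessarily acyclic (shared ancestors form
    # diamonds, which are fine)


def _lines(path: str | Path) -> Iterable[str]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip():
                yield line
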
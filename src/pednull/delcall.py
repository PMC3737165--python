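"""Candidate deletion calling from linked null alleles at adjacent SNPs.

A null allele at a single SNP may be a deletion or merely a polymorphism
under a primer site; null alleles at *adjacent* markers carried by the
same individuals are the signature of a deletion spanning both. A region
is called when, within one family, an F1 parent and at least three F2
individuals show evidence of linked null alleles at two consecutive
markers of the map. Calls supported independently by both families are
merged. The size estimate is simply the distance between the two marker
positions (the true deletion extends an unknown distance beyond them).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .classify import IntegratedClassification, SNPFamilyClassification
from .pedmodel import Marker


@dataclass
class DeletionCall:
    chromosome: str
    first_marker: str
    first_position: int
    second_marker: str
    second_position: int
    families: list[str]
    carrier_parents: list[str]
    shared_f2_carriers: dict[str, frozenset[str]]  # family -> carrier set
    classes: list[str]
    run: bool = False  # part of a >2-marker run of linked nulls

    @property
    def size_kb(self) -> float:
        return round((self.second_position - self.first_position) / 1000, 1)


def _carrier_candidates(
    fc: SNPFamilyClassification,
) -> list[tuple[str, frozenset[str]]]:
    """(carrier F1 parent, putative F2 carrier set) pairs supported at a
    null-classified SNP in one family.

    Incompatibility-based classes use the F2 whose calls each hypothesis
    explains via a transmitted null; for the class-5 missing pattern the
    missing F2 themselves are the putative null homozygotes (implicating
    both parents when no explicit hypothesis survives).
    """
    if not fc.is_null_class:
        return []
    out: list[tuple[str, frozenset[str]]] = []
    for hyp in fc.hypotheses:
        for pid in hyp.carrier_parent_ids:
            out.append((pid, hyp.f2_carriers))
    if fc.category == "class5" and not out and fc.missing_f2:
        out.append(("*", fc.missing_f2))
    return out


def call_deletions(
    classifications: list[IntegratedClassification],
    markers: list[Marker],
    min_f2_carriers: int = 3,
) -> list[DeletionCall]:
    """Scan consecutive marker pairs for linked null alleles.

    ``markers`` must be sorted by (chromosome, position); pairs never span
    a chromosome boundary. A pair is called for a family when some null
    hypothesis at each marker names the same carrier F1 parent and the two
    putative F2 carrier sets share at least ``min_f2_carriers``
    individuals.
    """
    for a, b in zip(markers, markers[1:]):
        if (a.chromosome, a.position) > (b.chromosome, b.position):
            raise ValueError(
                f"marker map not sorted by (chromosome, position) at {b.id!r}"
            )
    by_marker = {ic.marker_id: ic for ic in classifications}
    calls: list[DeletionCall] = []
    supported_pairs: dict[tuple[str, str], set[tuple[str, str]]] = {}

    for m1, m2 in zip(markers, markers[1:]):
        if m1.chromosome != m2.chromosome:
            continue
        ic1, ic2 = by_marker.get(m1.id), by_marker.get(m2.id)
        if ic1 is None or ic2 is None:
            continue
        families: list[str] = []
        parents: list[str] = []
        carrier_sets: dict[str, frozenset[str]] = {}
        classes: list[str] = []
        for fc1 in ic1.per_family:
            fc2 = ic2.family_result(fc1.family_label)
            if fc2 is None:
                continue
            best: tuple[str, frozenset[str]] | None = None
            for p1, set1 in _carrier_candidates(fc1):
                for p2, set2 in _carrier_candidates(fc2):
                    if p1 != p2 and "*" not in (p1, p2):
                        continue
                    shared = set1 & set2
                    if len(shared) < min_f2_carriers:
                        continue
                    if best is None or len(shared) > len(best[1]):
                        parent = p2 if p1 == "*" else p1
                        best = (parent, frozenset(shared))
            if best is not None:
                families.append(fc1.family_label)
                if best[0] not in parents:
                    parents.append(best[0])
                carrier_sets[fc1.family_label] = best[1]
                for cat in (fc1.category, fc2.category):
                    if cat not in classes:
                        classes.append(cat)
                supported_pairs.setdefault(
                    (m1.id, m2.id), set()
                ).add((fc1.family_label, best[0]))
        if families:
            calls.append(
                DeletionCall(
                    chromosome=m1.chromosome,
                    first_marker=m1.id,
                    first_position=m1.position,
                    second_marker=m2.id,
                    second_position=m2.position,
                    families=families,
                    carrier_parents=parents,
                    shared_f2_carriers=carrier_sets,
                    classes=sorted(classes),
                )
            )

    # annotate runs: consecutive called pairs sharing family + carrier parent
    for c1, c2 in zip(calls, calls[1:]):
        if c1.second_marker != c2.first_marker:
            continue
        k1 = supported_pairs[(c1.first_marker, c1.second_marker)]
        k2 = supported_pairs[(c2.first_marker, c2.second_marker)]
        if k1 & k2:
            c1.run = True
            c2.run = True
    return calls


def write_regions(
    calls: list[DeletionCall], bed_path: str | Path, tsv_path: str | Path
) -> None:
    """Write calls as BED (0-based half-open) and a region TSV."""
    with open(bed_path, "w") as fh:
        for i, c in enumerate(calls, start=1):
            fh.write(
                f"{c.chromosome}\t{c.first_position - 1}\t{c.second_position}"
                f"\tregion_{i}\n"
            )
    with open(tsv_path, "w") as fh:
        fh.write(
            "region\tchrom\tsnps\tclasses\tfirst_position\tsecond_position\t"
            "size_kb\tfamilies\tcarrier_parents\tn_shared_f2\trun\n"
        )
        for i, c in enumerate(calls, start=1):
            n_shared = ";".join(
                f"{fam}:{len(s)}" for fam, s in sorted(c.shared_f2_carriers.items())
            )
            fh.write(
                f"region_{i}\t{c.chromosome}\t{c.first_marker},{c.second_marker}\t"
                f"{','.join(c.classes)}\t{c.first_position}\t{c.second_position}\t"
                f"{c.size_kb}\t{','.join(c.families)}\t"
                f"{','.join(c.carrier_parents)}\t{n_shared}\t"
                f"{'yes' if c.run else 'no'}\n"
            )
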
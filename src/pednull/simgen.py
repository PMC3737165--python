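"""Gene-drop simulator for three-generation intercross families.

Emulates the study design the detection method targets: a single F0
grandfather shared by all F1 parents, three F0 grandmothers (the F1 dams
of the two families sharing one of them), two F1 parents per family, and
~23-25 F2 offspring per family. Null alleles and multi-marker deletion
runs are injected into founder haplotypes and transmitted by Mendelian
segregation; markers are unlinked except within a deletion run, which
travels as one haplotype block (the regions of interest are tens of kb,
where recombination is negligible at this pedigree size).

The simulator also emits a truth table so detection recall can be
measured against the injected mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pedmodel import Call, CallMatrix, Family, Individual, Marker, Pedigree

NULL = 0


@dataclass(frozen=True)
class NullInjection:
    """Replace one founder haplotype with null alleles over a marker run.

    ``start`` is a 0-based marker index; ``length`` > 1 makes the run a
    deletion spanning consecutive markers.
    """

    carrier: str
    start: int
    length: int = 1
    haplotype: int = 0


@dataclass
class SimConfig:
    """Study-design parameters; defaults mirror the two-family intercross
    (23 and 25 F2 offspring, shared grandfather, allele frequency 0.5 in
    both founder lines at segregating markers)."""

    n_markers: int = 200
    n_offspring: tuple[int, ...] = (23, 25)
    founder_allele_freq: float = 0.5
    marker_spacing: int = 100_000  # bp between adjacent markers
    chromosome: str = "1"
    null_injections: tuple[NullInjection, ...] = ()
    error_markers: tuple[int, ...] = ()  # one forced miscall each
    assay_failure_markers: tuple[int, ...] = ()  # (nearly) all F2 missing
    error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for rate in (self.error_rate, self.missing_rate, self.founder_allele_freq):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate out of [0, 1]: {rate}")
        for inj in self.null_injections:
            if inj.start < 0 or inj.start + inj.length > self.n_markers:
                raise ValueError(
                    f"null injection run [{inj.start}, {inj.start + inj.length}) "
                    f"falls outside the {self.n_markers}-marker map"
                )
            if inj.haplotype not in (0, 1):
                raise ValueError("haplotype must be 0 or 1")
        for idx in (*self.error_markers, *self.assay_failure_markers):
            if not 0 <= idx < self.n_markers:
                raise ValueError(f"marker index {idx} outside map")


@dataclass
class TruthTable:
    """Ground truth of a simulation run."""

    true_genotypes: dict[tuple[str, str], tuple[int, int]]
    mechanism: dict[str, str]  # marker -> none|null|error|assay_failure
    runs: list[dict] = field(default_factory=list)  # run_id, carrier, markers


def build_pedigree(n_offspring: tuple[int, ...] = (23, 25)) -> Pedigree:
    """The intercross topology: every F1 sired by one grandfather, the two
    families' F1 dams sharing a grandmother."""
    roster: dict[str, Individual] = {}
    gf = Individual("GF", "F0")
    roster["GF"] = gf
    n_fam = len(n_offspring)
    gm_ids = [f"GM{i + 1}" for i in range(n_fam + 1)]
    for gid in gm_ids:
        roster[gid] = Individual(gid, "F0")
    families: list[Family] = []
    for f in range(n_fam):
        sire = Individual(f"F1_{2 * f + 1}", "F1", sire="GF", dam=gm_ids[f])
        dam = Individual(f"F1_{2 * f + 2}", "F1", sire="GF", dam=gm_ids[f + 1])
        roster[sire.id] = sire
        roster[dam.id] = dam
        offspring = []
        for k in range(n_offspring[f]):
            off = Individual(
                f"F2_{f + 1}_{k + 1:02d}", "F2", sire=sire.id, dam=dam.id
            )
            roster[off.id] = off
            offspring.append(off)
        families.append(
            Family(label=str(f + 1), parents=(sire, dam), offspring=offspring)
        )
    return Pedigree(individuals=roster, families=families)


def observe(true_genotype: tuple[int, int]) -> Call:
    """Observation model: a hemizygous carrier is called homozygous for its
    visible allele; a null homozygote yields a missing call."""
    a, b = true_genotype
    if a == NULL and b == NULL:
        return None
    if a == NULL:
        return (b, b)
    if b == NULL:
        return (a, a)
    return (a, b) if a <= b else (b, a)


def _meiosis(
    haplotypes: np.ndarray, rng: np.random.Generator, runs: list[tuple[int, int]]
) -> np.ndarray:
    """One gamete: independent chromosome choice per marker, except within
    deletion runs, which segregate as a single block."""
    n = haplotypes.shape[1]
    choice = rng.integers(0, 2, size=n)
    for start, length in runs:
        choice[start : start + length] = choice[start]
    return haplotypes[choice, np.arange(n)]


def simulate(config: SimConfig) -> tuple[CallMatrix, Pedigree, TruthTable]:
    """Run the gene drop; deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pedigree = build_pedigree(config.n_offspring)
    markers = [
        Marker(
            id=f"snp{i + 1:05d}",
            chromosome=config.chromosome,
            position=(i + 1) * config.marker_spacing,
        )
        for i in range(config.n_markers)
    ]
    n = config.n_markers
    runs = [
        (inj.start, inj.length) for inj in config.null_injections if inj.length > 1
    ]

    # founder haplotypes
    haplos: dict[str, np.ndarray] = {}
    f0_ids = [i.id for i in pedigree.individuals.values() if i.generation == "F0"]
    for ind_id in f0_ids:
        draws = rng.random((2, n))
        haplos[ind_id] = np.where(draws < config.founder_allele_freq, 1, 2).astype(
            np.int8
        )
    for inj in config.null_injections:
        if inj.carrier not in haplos:
            raise ValueError(f"injection carrier {inj.carrier!r} is not an F0")
        haplos[inj.carrier][inj.haplotype, inj.start : inj.start + inj.length] = NULL

    # gene drop through F1 then F2 (paternal haplotype first)
    for gen in ("F1", "F2"):
        for ind in pedigree.individuals.values():
            if ind.generation != gen:
                continue
            haplos[ind.id] = np.stack(
                [
                    _meiosis(haplos[ind.sire], rng, runs),
                    _meiosis(haplos[ind.dam], rng, runs),
                ]
            )

    ind_order = list(pedigree.individuals)
    truth_genotypes: dict[tuple[str, str], tuple[int, int]] = {}
    matrix = CallMatrix(markers=markers, individuals=ind_order)
    for ind_id in ind_order:
        h = haplos[ind_id]
        for i, marker in enumerate(markers):
            g = (int(h[0, i]), int(h[1, i]))
            truth_genotypes[(marker.id, ind_id)] = g
            matrix.set(marker.id, ind_id, observe(g))

    mechanism = {m.id: "none" for m in markers}
    touched = set()
    for inj in config.null_injections:
        for i in range(inj.start, inj.start + inj.length):
            mechanism[markers[i].id] = "null"
            touched.add(i)
    truth_runs = []
    for run_id, inj in enumerate(
        (j for j in config.null_injections if j.length > 1), start=1
    ):
        truth_runs.append(
            {
                "run_id": run_id,
                "carrier": inj.carrier,
                "markers": [
                    markers[i].id for i in range(inj.start, inj.start + inj.length)
                ],
            }
        )

    # forced single miscalls
    f12_ids = [
        i.id
        for i in pedigree.individuals.values()
        if i.generation in ("F1", "F2")
    ]
    for idx in config.error_markers:
        mid = markers[idx].id
        victim = f12_ids[int(rng.integers(0, len(f12_ids)))]
        matrix.set(mid, victim, _substitute(matrix.get(mid, victim), rng))
        mechanism[mid] = "error"
    # assay failures: all F2 lose their calls
    for idx in config.assay_failure_markers:
        mid = markers[idx].id
        for fam in pedigree.families:
            for off in fam.offspring:
                matrix.set(mid, off.id, None)
        mechanism[mid] = "assay_failure"

    if config.error_rate > 0 or config.missing_rate > 0:
        matrix = add_noise(
            matrix,
            config.error_rate,
            config.missing_rate,
            seed=int(rng.integers(0, 2**31)),
        )
    truth = TruthTable(
        true_genotypes=truth_genotypes, mechanism=mechanism, runs=truth_runs
    )
    return matrix, pedigree, truth


def _substitute(call: Call, rng: np.random.Generator) -> tuple[int, int]:
    options = [g for g in ((1, 1), (1, 2), (2, 2)) if g != call]
    return options[int(rng.integers(0, len(options)))]


def add_noise(
    matrix: CallMatrix, error_rate: float, missing_rate: float, seed: int
) -> CallMatrix:
    """Independently miscall each non-missing genotype with probability
    ``error_rate`` (uniform over the other two genotypes), then drop each
    call with probability ``missing_rate``. Returns a new matrix."""
    rng = np.random.default_rng(seed)
    out = CallMatrix(markers=list(matrix.markers), individuals=list(matrix.individuals))
    for marker in matrix.markers:
        for ind in matrix.individuals:
            call = matrix.get(marker.id, ind)
            if call is not None and error_rate > 0 and rng.random() < error_rate:
                call = _substitute(call, rng)
            if missing_rate > 0 and rng.random() < missing_rate:
                call = None
            out.set(marker.id, ind, call)
    return out


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------


def write_truth(truth: TruthTable, path: str | Path) -> None:
    """Long-format TSV: one row per (marker, individual) with the true
    alleles (0 = null), the marker's injected mechanism, and the deletion
    run id when the marker belongs to one."""
    run_of_marker: dict[str, tuple[int, str]] = {}
    for run in truth.runs:
        for mid in run["markers"]:
            run_of_marker[mid] = (run["run_id"], run["carrier"])
    with open(path, "w") as fh:
        fh.write("marker\tindividual\tallele1\tallele2\tmechanism\trun_id\tcarrier\n")
        for (mid, ind), (a, b) in truth.true_genotypes.items():
            run_id, carrier = run_of_marker.get(mid, (0, "-"))
            fh.write(
                f"{mid}\t{ind}\t{a}\t{b}\t{truth.mechanism.get(mid, 'none')}\t"
                f"{run_id}\t{carrier}\n"
            )


def read_truth(path: str | Path) -> TruthTable:
    true_genotypes: dict[tuple[str, str], tuple[int, int]] = {}
    mechanism: dict[str, str] = {}
    runs: dict[int, dict] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("marker\t"):
            raise ValueError(f"{path}: not a truth table")
        for line in fh:
            if not line.strip():
                continue
            mid, ind, a, b, mech, run_id, carrier = line.rstrip("\n").split("\t")
            true_genotypes[(mid, ind)] = (int(a), int(b))
            mechanism[mid] = mech
            rid = int(run_id)
            if rid:
                run = runs.setdefault(
                    rid, {"run_id": rid, "carrier": carrier, "markers": []}
                )
                if mid not in run["markers"]:
                    run["markers"].append(mid)
    return TruthTable(
        true_genotypes=true_genotypes,
        mechanism=mechanism,
        runs=[runs[k] for k in sorted(runs)],
    )


def simulate_mixture_counts(
    n_markers: int,
    error_fraction: float,
    error_ratio: float,
    detect_prob: float,
    seed: int,
) -> tuple[int, int]:
    """Simulate per-family detection counts for a class that is a mixture
    of null-allele SNPs (equal family rates) and genotyping-error SNPs
    (family-1 : family-2 rate ratio ``error_ratio``).

    Each marker is an error SNP with probability ``error_fraction``; null
    SNPs are detected in each family with ``detect_prob``, error SNPs with
    ``detect_prob * error_ratio`` in family 1 and ``detect_prob`` in
    family 2. Returns (family-1 count, family-2 count), from which the
    mixture estimator should recover ``error_fraction``.
    """
    if not 0 <= detect_prob * error_ratio <= 1:
        raise ValueError("detect_prob * error_ratio must stay within [0, 1]")
    rng = np.random.default_rng(seed)
    is_error = rng.random(n_markers) < error_fraction
    p1 = np.where(is_error, detect_prob * error_ratio, detect_prob)
    p2 = np.full(n_markers, detect_prob)
    n1 = int((rng.random(n_markers) < p1).sum())
    n2 = int((rng.random(n_markers) < p2).sum())
    return n1, n2
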
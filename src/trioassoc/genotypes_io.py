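"""Cohort data model and PLINK text PED/MAP input/output.

Genotypes are stored as minor-allele dosage (0, 1, 2) with ``MISSING`` (-1)
for untyped calls.  The minor allele is determined once, on the full sample
at load time, and then frozen: per-group frequencies above 0.5 are
legitimate, and odds ratios downstream stay oriented to a single effect
allele across every group contrast.

The PED dialect accepted here is deliberately permissive: any run of
whitespace separates tokens, the sex and phenotype columns are read but not
validated, and ``0`` denotes a missing allele.  Coordinates are 1-based
base pairs (GRCh37) carried as opaque metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING: int = -1

#: phenotype-column spellings translated to group labels on read (and back
#: on write); any other token is kept verbatim as the group label.
_PHENO_TO_GROUP = {"2": "CASE", "1": "CONTROL"}
_GROUP_TO_PHENO = {"CASE": "2", "CONTROL": "1"}


class PedMapParseError(ValueError):
    """Malformed PED/MAP content (bad column count, bad field)."""


class TriAllelicError(ValueError):
    """More than two distinct alleles observed at one marker."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with a fixed minor/major allele orientation."""

    id: str
    chrom: str
    pos: int
    allele_minor: str
    allele_major: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"{self.id}: position must be positive, got {self.pos}")
        if self.allele_minor == self.allele_major:
            raise ValueError(f"{self.id}: minor and major allele must differ")


@dataclass(frozen=True)
class Individual:
    iid: str
    fid: str
    sex: int = 0
    group: str = "UNKNOWN"


@dataclass
class Cohort:
    """An ordered marker panel plus an individuals-by-markers dosage matrix.

    ``genotypes[i, j]`` is the number of copies of ``markers[j].allele_minor``
    carried by ``individuals[i]`` (0, 1, 2) or ``MISSING``.
    """

    markers: list[Marker]
    individuals: list[Individual]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise ValueError(f"invalid dosage values {bad.tolist()}; expected 0/1/2/missing")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids in panel")

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        for j, m in enumerate(self.markers):
            if m.id == marker_id:
                return j
        raise KeyError(f"unknown marker {marker_id!r}")

    def group_labels(self) -> set[str]:
        return {ind.group for ind in self.individuals}

    def group_indices(self, groups: Iterable[str] | None = None) -> np.ndarray:
        """Row indices of individuals whose group is in ``groups`` (all if None)."""
        if groups is None:
            return np.arange(self.n_individuals)
        groups = set(groups)
        unknown = groups - self.group_labels()
        if unknown:
            raise KeyError(f"unknown group label(s) {sorted(unknown)}")
        mask = np.array([ind.group in groups for ind in self.individuals])
        return np.flatnonzero(mask)

    def dosages(self, marker_id: str, groups: Iterable[str] | None = None) -> np.ndarray:
        return self.genotypes[self.group_indices(groups), self.marker_index(marker_id)]

    # -- derived cohorts -----------------------------------------------------

    def select_markers(self, marker_ids: Sequence[str]) -> "Cohort":
        idx = [self.marker_index(m) for m in marker_ids]
        return Cohort(
            markers=[self.markers[j] for j in idx],
            individuals=list(self.individuals),
            genotypes=self.genotypes[:, idx].copy(),
        )

    def subset(self, rows: Sequence[int]) -> "Cohort":
        rows = list(rows)
        return Cohort(
            markers=list(self.markers),
            individuals=[self.individuals[i] for i in rows],
            genotypes=self.genotypes[rows, :].copy(),
        )

    @staticmethod
    def concat(cohorts: Sequence["Cohort"]) -> "Cohort":
        """Stack cohorts sharing an identical marker panel."""
        if not cohorts:
            raise ValueError("nothing to concatenate")
        panel = cohorts[0].markers
        for c in cohorts[1:]:
            if c.markers != panel:
                raise ValueError("marker panels differ; cannot concatenate")
        return Cohort(
            markers=list(panel),
            individuals=[ind for c in cohorts for ind in c.individuals],
            genotypes=np.vstack([c.genotypes for c in cohorts]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.individuals == other.individuals
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(frozen=True)
class TrioSet:
    """Father/mother/child row triples indexing into a Cohort."""

    trios: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        children = [c for _, _, c in self.trios]
        if len(set(children)) != len(children):
            raise ValueError("a child appears in more than one trio")
        for f, m, c in self.trios:
            if len({f, m, c}) != 3:
                raise ValueError(f"trio ({f}, {m}, {c}) indices must be distinct")

    def __len__(self) -> int:
        return len(self.trios)

    def validate(self, cohort: Cohort) -> None:
        n = cohort.n_individuals
        for f, m, c in self.trios:
            if not (0 <= f < n and 0 <= m < n and 0 <= c < n):
                raise IndexError(f"trio ({f}, {m}, {c}) out of range for cohort of {n}")

    def founder_indices(self) -> np.ndarray:
        return np.unique([i for f, m, _ in self.trios for i in (f, m)])

    def child_indices(self) -> np.ndarray:
        return np.array([c for _, _, c in self.trios], dtype=int)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one marker over one sample subset."""

    n_hom_minor: int
    n_het: int
    n_hom_major: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hom_minor", "n_het", "n_hom_major", "n_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_genotyped(self) -> int:
        return self.n_hom_minor + self.n_het + self.n_hom_major

    @property
    def n_total(self) -> int:
        return self.n_genotyped + self.n_missing

    @property
    def allele_count_minor(self) -> int:
        return 2 * self.n_hom_minor + self.n_het

    @property
    def allele_count_major(self) -> int:
        return 2 * self.n_hom_major + self.n_het

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency; None when every genotype is missing."""
        total = self.allele_count_minor + self.allele_count_major
        if total == 0:
            return None
        return self.allele_count_minor / total

    @property
    def missing_rate(self) -> float:
        if self.n_total == 0:
            return 0.0
        return self.n_missing / self.n_total

    @classmethod
    def from_dosages(cls, dosages: np.ndarray) -> "GenotypeCounts":
        d = np.asarray(dosages)
        return cls(
            n_hom_minor=int((d == 2).sum()),
            n_het=int((d == 1).sum()),
            n_hom_major=int((d == 0).sum()),
            n_missing=int((d == MISSING).sum()),
        )

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_hom_minor + other.n_hom_minor,
            self.n_het + other.n_het,
            self.n_hom_major + other.n_hom_major,
            self.n_missing + other.n_missing,
        )


def genotype_counts(
    cohort: Cohort, marker_id: str, groups: Iterable[str] | None = None
) -> GenotypeCounts:
    """Genotype counts for one marker over the individuals in ``groups``."""
    return GenotypeCounts.from_dosages(cohort.dosages(marker_id, groups))


# ---------------------------------------------------------------------------
# PED/MAP I/O


def read_pedmap(ped_path: str | Path, map_path: str | Path) -> tuple[Cohort, TrioSet]:
    """Read whitespace-separated PED/MAP files into a Cohort.

    The minor allele at each marker is the rarer allele over the whole file
    (lexicographically smaller on ties).  Allele pairs containing ``0`` are
    coded missing.  Trio links are built wherever the father and mother id
    columns resolve to rows of the same family in the file.

    Returns the cohort and the (possibly empty) inferred TrioSet.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)

    map_rows: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) < 4:
            raise PedMapParseError(
                f"{map_path} line {lineno}: expected 4 columns "
                f"(chrom, id, cM, pos), got {len(tokens)}"
            )
        chrom, mid, _cm, pos = tokens[:4]
        map_rows.append((chrom, mid, int(pos)))
    n_markers = len(map_rows)

    rows: list[list[str]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        tokens = line.split()
        expected = 6 + 2 * n_markers
        if len(tokens) != expected:
            raise PedMapParseError(
                f"{ped_path} line {lineno}: expected {expected} columns "
                f"for {n_markers} markers, got {len(tokens)}"
            )
        rows.append(tokens)

    # allele inventory -> minor/major designation per marker
    markers: list[Marker] = []
    allele_pairs: list[tuple[str, str]] = []
    for j, (chrom, mid, pos) in enumerate(map_rows):
        counts: dict[str, int] = {}
        for t in rows:
            for a in (t[6 + 2 * j], t[7 + 2 * j]):
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise TriAllelicError(
                f"marker {mid}: {len(counts)} distinct alleles {sorted(counts)}"
            )
        if len(counts) == 2:
            (a1, c1), (a2, c2) = sorted(counts.items())
            minor, major = (a1, a2) if c1 <= c2 else (a2, a1)
        elif len(counts) == 1:
            major = next(iter(counts))
            minor = "."
        else:
            minor, major = ".", "N"
        markers.append(Marker(mid, chrom, pos, minor, major))
        allele_pairs.append((minor, major))

    genotypes = np.full((len(rows), n_markers), MISSING, dtype=np.int8)
    individuals: list[Individual] = []
    parent_ids: list[tuple[str, str, str]] = []  # (fid, pat_iid, mat_iid)
    key_to_row: dict[tuple[str, str], int] = {}
    for i, t in enumerate(rows):
        fid, iid, pat, mat, sex_tok, pheno = t[:6]
        try:
            sex = int(sex_tok)
        except ValueError:
            sex = 0
        group = _PHENO_TO_GROUP.get(pheno, pheno)
        individuals.append(Individual(iid=iid, fid=fid, sex=sex, group=group))
        parent_ids.append((fid, pat, mat))
        key_to_row[(fid, iid)] = i
        for j in range(n_markers):
            a, b = t[6 + 2 * j], t[7 + 2 * j]
            if a == "0" or b == "0":
                continue
            minor = allele_pairs[j][0]
            genotypes[i, j] = (a == minor) + (b == minor)

    trios = []
    for i, (fid, pat, mat) in enumerate(parent_ids):
        if pat == "0" or mat == "0":
            continue
        f = key_to_row.get((fid, pat))
        m = key_to_row.get((fid, mat))
        if f is not None and m is not None and len({f, m, i}) == 3:
            trios.append((f, m, i))

    cohort = Cohort(markers=markers, individuals=individuals, genotypes=genotypes)
    return cohort, TrioSet(trios=tuple(trios))


def write_pedmap(
    cohort: Cohort,
    ped_path: str | Path,
    map_path: str | Path,
    trioset: TrioSet | None = None,
) -> None:
    """Write a Cohort as whitespace-separated PED/MAP, re-readable losslessly.

    When a TrioSet is given, the father/mother id columns of each child row
    are filled so that :func:`read_pedmap` re-infers the same trios.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)

    with map_path.open("w") as fh:
        for m in cohort.markers:
            fh.write(f"{m.chrom}\t{m.id}\t0\t{m.pos}\n")

    child_parents: dict[int, tuple[str, str]] = {}
    if trioset is not None:
        trioset.validate(cohort)
        for f, m, c in trioset.trios:
            child_parents[c] = (cohort.individuals[f].iid, cohort.individuals[m].iid)

    with ped_path.open("w") as fh:
        for i, ind in enumerate(cohort.individuals):
            pat, mat = child_parents.get(i, ("0", "0"))
            pheno = _GROUP_TO_PHENO.get(ind.group, ind.group)
            fields = [ind.fid, ind.iid, pat, mat, str(ind.sex), pheno]
            for j, m in enumerate(cohort.markers):
                g = int(cohort.genotypes[i, j])
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [m.allele_major, m.allele_major]
                elif g == 1:
                    fields += [m.allele_minor, m.allele_major]
                else:
                    fields += [m.allele_minor, m.allele_minor]
            fh.write("\t".join(fields) + "\n")
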
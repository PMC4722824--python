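"""Data model and I/O for sequence alignments, microsatellite genotypes and
population maps.

Formats handled here are plain text: FASTA for aligned sequences, GenePop for
diploid microsatellite genotypes, and a three-column TSV
(``individual<TAB>population<TAB>group``) mapping individuals to sampling
localities and localities to higher-level geographic groups.

Conventions
-----------
* Alignment alphabet is restricted to ``A C G T N -``.  Sites involving ``N``
  or ``-`` are excluded *pairwise* in distance computations (see
  :mod:`scenabc.sumstats`), never listwise.
* Microsatellite alleles are stored as strictly positive integer repeat
  counts; missing data is encoded as ``-1`` in the call array.
* Individual identifiers are case-sensitive exact strings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_SYMBOLS = frozenset("ACGTN-")

#: integer encoding used throughout sumstats: A,C,G,T -> 0..3; N -> 4; '-' -> 5
SYMBOL_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
CODE_SYMBOLS = np.array(list("ACGTN-"))


class AlignmentError(ValueError):
    """Raised when sequences violate alignment invariants."""


class ParseError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# sequence alignments
# ---------------------------------------------------------------------------


@dataclass
class SequenceAlignment:
    """An aligned set of nucleotide sequences.

    Parameters
    ----------
    ids
        Unique individual identifiers, one per row.
    seqs
        ``(n, L)`` array of single-character symbols from ``{A,C,G,T,N,-}``.
    """

    ids: list[str]
    seqs: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.seqs = np.asarray(self.seqs, dtype="U1")
        if self.seqs.ndim != 2:
            raise AlignmentError("sequence matrix must be 2-D")
        if len(self.ids) != self.seqs.shape[0]:
            raise AlignmentError(
                f"{len(self.ids)} ids but {self.seqs.shape[0]} sequence rows"
            )
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        bad = set(np.unique(self.seqs)) - VALID_SYMBOLS
        if bad:
            raise AlignmentError(f"illegal symbols in alignment: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    def encoded(self) -> np.ndarray:
        """Return the alignment as uint8 codes (A,C,G,T,N,- -> 0..5)."""
        out = np.empty(self.seqs.shape, dtype=np.uint8)
        for sym, code in SYMBOL_CODES.items():
            out[self.seqs == sym] = code
        return out

    def subset(self, ids: Sequence[str]) -> "SequenceAlignment":
        index = {v: i for i, v in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        rows = [index[i] for i in ids]
        return SequenceAlignment(list(ids), self.seqs[rows])


def read_alignment(path: str | Path) -> SequenceAlignment:
    """Read a FASTA file into a :class:`SequenceAlignment`.

    Record order is preserved.  Ragged record lengths raise
    :class:`AlignmentError`; any symbol outside ``{A,C,G,T,N,-}`` raises
    :class:`ParseError` naming the record and position (case is folded to
    upper before validation; U is accepted and mapped to T).
    """
    path = Path(path)
    ids: list[str] = []
    chunks: list[str] = []
    current: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    chunks.append("".join(current))
                ids.append(line[1:].split()[0] if len(line) > 1 else "")
                current = []
            else:
                if current is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before header")
                current.append(line.upper().replace("U", "T"))
        if current is not None:
            chunks.append("".join(current))
    if not ids:
        raise ParseError(f"{path}: no FASTA records found")
    for rid, seq in zip(ids, chunks):
        for pos, sym in enumerate(seq, 1):
            if sym not in VALID_SYMBOLS:
                raise ParseError(
                    f"{path}: record {rid!r} position {pos}: illegal symbol {sym!r}"
                )
    lengths = {len(s) for s in chunks}
    if len(lengths) > 1:
        raise AlignmentError(
            f"{path}: ragged alignment, record lengths {sorted(lengths)}"
        )
    mat = np.array([list(s) for s in chunks], dtype="U1")
    return SequenceAlignment(ids, mat)


def write_alignment(aln: SequenceAlignment, path: str | Path, wrap: int = 70) -> None:
    """Write an alignment as FASTA (fixed line wrap, default 70 columns)."""
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.seqs):
            fh.write(f">{rid}\n")
            seq = "".join(row)
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# microsatellite genotypes
# ---------------------------------------------------------------------------


@dataclass
class MicrosatGenotypes:
    """Diploid genotypes at a set of microsatellite loci.

    ``calls`` has shape ``(n_individuals, n_loci, 2)``; alleles are strictly
    positive integers (repeat units), missing cells hold ``-1`` in both slots.
    Allele order within a cell is not meaningful (unordered pair); calls are
    stored sorted.
    """

    ids: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.loci = list(self.loci)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.ids)}, {len(self.loci)}, 2)"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in genotypes")
        half_missing = (self.calls == -1).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("cells must carry exactly two alleles or be missing")
        present = self.calls[self.calls != -1]
        if present.size and (present <= 0).any():
            raise ValueError("allele sizes must be strictly positive")
        self.calls = np.sort(self.calls, axis=2)
        # missing cells sort to (-1, -1) which is fine

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, ids: Sequence[str]) -> "MicrosatGenotypes":
        index = {v: i for i, v in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"ids not in genotypes: {missing}")
        rows = [index[i] for i in ids]
        return MicrosatGenotypes(list(ids), self.loci, self.calls[rows])


_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def read_genepop(path: str | Path) -> tuple[MicrosatGenotypes, dict[str, str]]:
    """Read a GenePop file (2- or 3-digit allele coding).

    Returns the genotypes plus an ``individual -> population`` mapping where
    populations are named ``pop1, pop2, ...`` in file order (GenePop does not
    name populations; the last individual label of each block is the
    community convention but is not unique in practice).

    ``000``/``00`` allele codes map to missing.  An odd-length allele field
    raises :class:`ParseError`.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError(f"{path}: empty file")
    # line 1 = title; locus names until first Pop (one per line or comma-separated)
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and not _POP_RE.match(body[i].strip()):
        chunk = body[i].strip()
        if chunk:
            loci.extend([c.strip() for c in chunk.split(",") if c.strip()])
        i += 1
    if i == len(body):
        raise ParseError(f"{path}: no 'Pop' separator found")
    if not loci:
        raise ParseError(f"{path}: no locus names before first 'Pop'")

    ids: list[str] = []
    pops: dict[str, str] = {}
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    for line in body[i:]:
        stripped = line.strip()
        if not stripped:
            continue
        if _POP_RE.match(stripped):
            pop_idx += 1
            continue
        if "," not in stripped:
            raise ParseError(f"{path}: genotype line without ',' separator: {line!r}")
        name, geno = stripped.split(",", 1)
        name = name.strip()
        fields = geno.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"{path}: individual {name!r} has {len(fields)} genotype "
                f"fields, expected {len(loci)}"
            )
        calls = []
        for locus, f in zip(loci, fields):
            if len(f) % 2 != 0 or not f.isdigit():
                raise ParseError(
                    f"{path}: individual {name!r} locus {locus!r}: bad allele "
                    f"field {f!r}"
                )
            half = len(f) // 2
            if half not in (2, 3):
                raise ParseError(
                    f"{path}: individual {name!r} locus {locus!r}: allele "
                    f"coding must be 2 or 3 digits, got field {f!r}"
                )
            a, b = int(f[:half]), int(f[half:])
            calls.append((a if a > 0 else -1, b if b > 0 else -1))
        # one allele scored, one missing -> treat cell as missing
        calls = [(-1, -1) if (-1 in c) else c for c in calls]
        ids.append(name)
        pops[name] = f"pop{pop_idx}"
        rows.append(calls)
    if not ids:
        raise ParseError(f"{path}: no individuals found")
    arr = np.array(rows, dtype=np.int64)
    if (arr == -1).all():
        logger.warning("%s: all genotypes missing (all-zero allele codes)", path)
    geno = MicrosatGenotypes(ids, loci, arr)
    return geno, pops


def write_genepop(
    geno: MicrosatGenotypes,
    pops: Mapping[str, str],
    path: str | Path,
    title: str = "scenabc genepop export",
    digits: int = 3,
) -> None:
    """Write genotypes in GenePop format, one population block per value of
    ``pops`` (block order follows first appearance in ``geno.ids``)."""
    order: list[str] = []
    for ind in geno.ids:
        p = pops[ind]
        if p not in order:
            order.append(p)
    index = {v: i for i, v in enumerate(geno.ids)}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in geno.loci:
            fh.write(locus + "\n")
        for p in order:
            fh.write("Pop\n")
            for ind in geno.ids:
                if pops[ind] != p:
                    continue
                cell = geno.calls[index[ind]]
                parts = []
                for a, b in cell:
                    a = 0 if a < 0 else a
                    b = 0 if b < 0 else b
                    parts.append(f"{a:0{digits}d}{b:0{digits}d}")
                fh.write(f"{ind}, " + " ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------


@dataclass
class PopulationMap:
    """Individual -> population (sampling locality) -> group assignments."""

    individual_to_population: dict[str, str]
    population_to_group: dict[str, str]

    def __post_init__(self) -> None:
        for ind, pop in self.individual_to_population.items():
            if pop not in self.population_to_group:
                raise ValueError(f"individual {ind!r}: population {pop!r} has no group")

    @property
    def individuals(self) -> list[str]:
        return list(self.individual_to_population)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.individual_to_population.values()))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.population_to_group.values()))

    def group_of(self, individual: str) -> str:
        return self.population_to_group[self.individual_to_population[individual]]

    def individuals_in_group(self, group: str, among: Iterable[str]) -> list[str]:
        return [i for i in among if self.group_of(i) == group]

    def individuals_in_population(self, pop: str, among: Iterable[str]) -> list[str]:
        return [i for i in among if self.individual_to_population[i] == pop]

    def group_counts(self, among: Iterable[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ind in among:
            g = self.group_of(ind)
            counts[g] = counts.get(g, 0) + 1
        return counts


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a 3-column TSV map (header ``individual  population  group``)."""
    path = Path(path)
    ind2pop: dict[str, str] = {}
    pop2grp: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:3]] != ["individual", "population", "group"]:
            raise ParseError(
                f"{path}: expected header 'individual\\tpopulation\\tgroup', "
                f"got {header!r}"
            )
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            ind, pop, grp = (p.strip() for p in parts[:3])
            if ind in ind2pop:
                raise ParseError(f"{path}:{lineno}: duplicate individual {ind!r}")
            if pop in pop2grp and pop2grp[pop] != grp:
                raise ParseError(
                    f"{path}:{lineno}: population {pop!r} assigned to two "
                    f"groups ({pop2grp[pop]!r}, {grp!r})"
                )
            ind2pop[ind] = pop
            pop2grp[pop] = grp
    return PopulationMap(ind2pop, pop2grp)


def write_population_map(pmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\tgroup\n")
        for ind, pop in pmap.individual_to_population.items():
            fh.write(f"{ind}\t{pop}\t{pmap.population_to_group[pop]}\n")


# ---------------------------------------------------------------------------
# multilocus dataset
# ---------------------------------------------------------------------------


@dataclass
class MultilocusDataset:
    """Sequences and/or microsatellite genotypes plus the population map."""

    popmap: PopulationMap
    alignment: SequenceAlignment | None = None
    genotypes: MicrosatGenotypes | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alignment is None and self.genotypes is None:
            raise ValueError("dataset must carry at least one marker type")
        mapped = set(self.popmap.individual_to_population)
        for marker, obj in (("alignment", self.alignment), ("genotypes", self.genotypes)):
            if obj is None:
                continue
            unmapped = [i for i in obj.ids if i not in mapped]
            if unmapped:
                raise ValueError(
                    f"{marker} individuals missing from the population map: "
                    f"{unmapped}"
                )

    @property
    def groups(self) -> list[str]:
        return self.popmap.groups

    def require_alignment(self) -> SequenceAlignment:
        if self.alignment is None:
            raise ValueError("operation requires sequence data, none present")
        return self.alignment

    def require_genotypes(self) -> MicrosatGenotypes:
        if self.genotypes is None:
            raise ValueError("operation requires microsatellite data, none present")
        return self.genotypes

    def group_alignment(self, group: str) -> SequenceAlignment:
        aln = self.require_alignment()
        ids = self.popmap.individuals_in_group(group, aln.ids)
        return aln.subset(ids)

    def group_genotypes(self, group: str) -> MicrosatGenotypes:
        geno = self.require_genotypes()
        ids = self.popmap.individuals_in_group(group, geno.ids)
        return geno.subset(ids)


def assemble_dataset(
    alignment: SequenceAlignment | None,
    genotypes: MicrosatGenotypes | None,
    map_file: str | Path,
) -> MultilocusDataset:
    """Combine markers with a population map file into a validated dataset."""
    pmap = read_population_map(map_file)
    return MultilocusDataset(popmap=pmap, alignment=alignment, genotypes=genotypes)
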
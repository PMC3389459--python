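"""Core genome data types and readers/writers for signed gene orders.

A genome is a named set of chromosomes (or assembly fragments); each
chromosome is a linear, signed order of genes.  The on-disk dialect is
GRIMM-style text: a ``>name`` header per genome, one whitespace-separated
line of signed gene tokens per chromosome, terminated by ``$`` (linear
chromosomes only; circular chromosomes are rejected).  A ``# wgd`` tag on
the header marks a whole-genome-duplication descendant, and a
``# fragment`` tag after the ``$`` marks an assembly fragment, which is
otherwise treated exactly like a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Hashable, Iterable, Mapping

__all__ = [
    "Gene",
    "Chromosome",
    "Genome",
    "GenomeError",
    "ParseError",
    "read_genome",
    "read_genomes",
    "write_genome",
    "write_genomes",
]


class GenomeError(ValueError):
    """Invalid genome structure (duplicate genes, empty chromosomes ...)."""


class ParseError(GenomeError):
    """Malformed gene-order text."""


@dataclass(frozen=True)
class Gene:
    """A gene occurrence in one genome.

    ``orthoset_id`` is the identifier of the orthology set the gene was
    assigned to (absent before orthology resolution).  ``copy_index`` is 1,
    or 2 for the second surviving copy of a duplicated gene in a WGD
    descendant.
    """

    genome_id: str
    gene_id: str
    orthoset_id: Hashable | None = None
    copy_index: int = 1


@dataclass(frozen=True)
class Chromosome:
    """A linear, signed gene order: tuple of ``(gene_id, sign)`` pairs."""

    genes: tuple[tuple[str, int], ...]
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise GenomeError("chromosome must contain at least one gene")
        seen = set()
        for gid, sign in self.genes:
            if sign not in (1, -1):
                raise GenomeError(f"gene {gid!r}: sign must be +1 or -1")
            if gid in seen:
                raise GenomeError(f"gene {gid!r} appears twice on one chromosome")
            seen.add(gid)

    def reversed_(self) -> "Chromosome":
        """The same chromosome read from the other end."""
        return Chromosome(
            tuple((g, -s) for g, s in reversed(self.genes)), self.is_fragment
        )

    def canonical(self) -> tuple:
        """Orientation-independent key: a chromosome equals its reverse."""
        rev = tuple((g, -s) for g, s in reversed(self.genes))
        return min(self.genes, rev)


class Genome:
    """A named set of chromosomes with unique gene ids.

    Equality is structural and orientation/order independent: genomes are
    unordered sets of chromosomes, and a chromosome is identified with its
    reverse complement.
    """

    def __init__(
        self,
        name: str,
        chromosomes: Iterable[Chromosome],
        is_wgd_descendant: bool = False,
        genes: Mapping[str, Gene] | None = None,
    ) -> None:
        self.name = name
        self.chromosomes = tuple(chromosomes)
        self.is_wgd_descendant = is_wgd_descendant
        seen: dict[str, Gene] = {}
        for chrom in self.chromosomes:
            for gid, _sign in chrom.genes:
                if gid in seen:
                    raise GenomeError(
                        f"genome {name!r}: gene {gid!r} appears more than once"
                    )
                if genes is not None and gid in genes:
                    seen[gid] = genes[gid]
                else:
                    seen[gid] = Gene(genome_id=name, gene_id=gid)
        self.genes: dict[str, Gene] = seen
        self._check_orthoset_multiplicity()

    # -- invariants -----------------------------------------------------

    def _check_orthoset_multiplicity(self) -> None:
        counts: dict[Hashable, int] = {}
        for g in self.genes.values():
            if g.orthoset_id is None:
                continue
            counts[g.orthoset_id] = counts.get(g.orthoset_id, 0) + 1
        limit = 2 if self.is_wgd_descendant else 1
        for os_id, c in counts.items():
            if c > limit:
                raise GenomeError(
                    f"genome {self.name!r}: orthology set {os_id!r} has {c} "
                    f"members (limit {limit})"
                )

    # -- basic queries --------------------------------------------------

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def gene_ids(self) -> set[str]:
        return set(self.genes)

    def orthoset_ids(self) -> set:
        return {
            g.orthoset_id for g in self.genes.values() if g.orthoset_id is not None
        }

    def signed_orders(
        self, by: str = "gene"
    ) -> list[tuple[tuple[Hashable, int], ...]]:
        """Chromosomes as tuples of ``(label, sign)``.

        ``by='gene'`` labels genes by gene id; ``by='orthoset'`` labels them
        by orthoset id (or ``(orthoset_id, copy_index)`` in a WGD
        descendant), dropping genes without an orthoset assignment.
        """
        out = []
        for chrom in self.chromosomes:
            row: list[tuple[Hashable, int]] = []
            for gid, sign in chrom.genes:
                if by == "gene":
                    row.append((gid, sign))
                elif by == "orthoset":
                    g = self.genes[gid]
                    if g.orthoset_id is None:
                        continue
                    label: Hashable = g.orthoset_id
                    if self.is_wgd_descendant:
                        label = (g.orthoset_id, g.copy_index)
                    row.append((label, sign))
                else:  # pragma: no cover - guarded by callers
                    raise ValueError(f"unknown labelling {by!r}")
            if row:
                out.append(tuple(row))
        return out

    # -- derived genomes ------------------------------------------------

    def restricted(self, keep: set[str]) -> "Genome":
        """Induced sub-genome on ``keep`` gene ids, preserving order/signs."""
        chroms = []
        for chrom in self.chromosomes:
            row = tuple((g, s) for g, s in chrom.genes if g in keep)
            if row:
                chroms.append(Chromosome(row, chrom.is_fragment))
        return Genome(
            self.name,
            chroms,
            self.is_wgd_descendant,
            genes={g: self.genes[g] for g in keep if g in self.genes},
        )

    def with_orthosets(self, assignment: Mapping[str, Hashable]) -> "Genome":
        """Copy of the genome with orthoset ids (and WGD copy indices) set.

        Genes absent from ``assignment`` keep ``orthoset_id=None``.  In a
        WGD descendant the two genes of a doubly-represented orthoset get
        copy indices 1 and 2 in order of appearance.
        """
        seen: dict[Hashable, int] = {}
        genes: dict[str, Gene] = {}
        for chrom in self.chromosomes:
            for gid, _s in chrom.genes:
                base = self.genes[gid]
                os_id = assignment.get(gid)
                if os_id is None:
                    genes[gid] = replace(base, orthoset_id=None, copy_index=1)
                    continue
                seen[os_id] = seen.get(os_id, 0) + 1
                genes[gid] = replace(
                    base, orthoset_id=os_id, copy_index=seen[os_id]
                )
        return Genome(self.name, self.chromosomes, self.is_wgd_descendant, genes)

    # -- equality -------------------------------------------------------

    def _key(self) -> tuple:
        return (
            self.name,
            self.is_wgd_descendant,
            tuple(
                sorted((c.canonical(), c.is_fragment) for c in self.chromosomes)
            ),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Genome({self.name!r}, {self.n_chromosomes} chromosomes, {len(self)} genes)"


# ---------------------------------------------------------------------------
# GRIMM-dialect IO
# ---------------------------------------------------------------------------


def _parse_chromosome_line(line: str, lineno: int) -> tuple[list[tuple[str, int]], bool]:
    body, _, comment = line.partition("#")
    is_fragment = "fragment" in comment.lower()
    tokens = body.split()
    if not tokens or tokens[-1] not in ("$", "@"):
        raise ParseError(f"line {lineno}: chromosome line must end with '$'")
    if tokens[-1] == "@":
        raise ParseError(f"line {lineno}: circular chromosomes are not supported")
    tokens = tokens[:-1]
    if not tokens:
        raise ParseError(f"line {lineno}: empty chromosome")
    genes = []
    for tok in tokens:
        if tok.startswith("-"):
            genes.append((tok[1:], -1))
        else:
            genes.append((tok.lstrip("+"), 1))
    return genes, is_fragment


def read_genomes(path: str | Path) -> dict[str, Genome]:
    """Parse a GRIMM-dialect file that may hold several genomes."""
    genomes: dict[str, Genome] = {}
    name: str | None = None
    wgd = False
    chroms: list[Chromosome] = []

    def flush() -> None:
        nonlocal name, wgd, chroms
        if name is None:
            return
        if name in genomes:
            raise ParseError(f"duplicate genome header {name!r}")
        try:
            genomes[name] = Genome(name, chroms, is_wgd_descendant=wgd)
        except GenomeError as exc:
            raise ParseError(str(exc)) from exc
        name, wgd, chroms = None, False, []

    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header, _, comment = line[1:].partition("#")
            name = header.strip()
            if not name:
                raise ParseError(f"line {lineno}: empty genome name")
            wgd = "wgd" in comment.lower()
            continue
        if name is None:
            raise ParseError(f"line {lineno}: chromosome before any '>' header")
        genes, is_fragment = _parse_chromosome_line(line, lineno)
        try:
            chroms.append(Chromosome(tuple(genes), is_fragment))
        except GenomeError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    flush()
    if not genomes:
        raise ParseError(f"{path}: no genomes found")
    return genomes


def read_genome(path: str | Path, name: str | None = None) -> Genome:
    """Read one genome; ``name`` selects it when the file holds several."""
    genomes = read_genomes(path)
    if name is None:
        if len(genomes) != 1:
            raise ParseError(
                f"{path}: file holds {len(genomes)} genomes; a name is required"
            )
        return next(iter(genomes.values()))
    if name not in genomes:
        raise ParseError(f"{path}: no genome named {name!r}")
    return genomes[name]


def format_genome(g: Genome) -> str:
    if not g.chromosomes:
        raise GenomeError(f"genome {g.name!r} has no chromosomes; nothing to write")
    lines = [f">{g.name} # wgd" if g.is_wgd_descendant else f">{g.name}"]
    for chrom in g.chromosomes:
        toks = " ".join(gid if s > 0 else f"-{gid}" for gid, s in chrom.genes)
        suffix = " $ # fragment" if chrom.is_fragment else " $"
        lines.append(toks + suffix)
    return "\n".join(lines) + "\n"


def write_genome(g: Genome, path: str | Path) -> None:
    Path(path).write_text(format_genome(g))


def write_genomes(genomes: Iterable[Genome], path: str | Path) -> None:
    Path(path).write_text("".join(format_genome(g) for g in genomes))
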
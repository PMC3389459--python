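"""Pairwise homology/synteny-block tables.

The canonical intermediate is a tab-delimited table with one homologous
gene pair per row, grouped into synteny blocks::

    genome_a  gene_a  chr_a  pos_a  strand_a  genome_b  gene_b  chr_b  pos_b  strand_b  block_id

Positions are 1-based order indices along each chromosome; strands are
``+``/``-``.  Block sizes (gene-pair counts) are computed on read; minimum
block-size filtering is applied downstream, when the homology graph is
built.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .genomes import Genome

__all__ = ["PairwiseHomologyTable", "HomologyTableError", "read_homology_tables",
           "write_homology_table"]

COLUMNS = [
    "genome_a", "gene_a", "chr_a", "pos_a", "strand_a",
    "genome_b", "gene_b", "chr_b", "pos_b", "strand_b",
    "block_id",
]


class HomologyTableError(ValueError):
    pass


@dataclass
class PairwiseHomologyTable:
    """All homologous gene pairs between one pair of genomes."""

    genome_a: str
    genome_b: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise HomologyTableError(f"missing columns: {missing}")
        if len(self.records):
            pairs = set(
                zip(self.records["genome_a"], self.records["genome_b"])
            )
            if pairs != {(self.genome_a, self.genome_b)}:
                raise HomologyTableError(
                    f"table mixes genome pairs: {sorted(pairs)}"
                )

    @property
    def block_sizes(self) -> dict:
        """Number of homologous gene pairs per block."""
        return self.records.groupby("block_id").size().to_dict()

    def pairs(self, min_block_size: int = 1) -> list[tuple[str, str]]:
        """(gene_a, gene_b) pairs from blocks with >= min_block_size pairs."""
        if min_block_size <= 1:
            df = self.records
        else:
            sizes = self.records.groupby("block_id")["gene_a"].transform("size")
            df = self.records[sizes >= min_block_size]
        return list(zip(df["gene_a"], df["gene_b"]))

    def blocks(self, min_block_size: int = 1) -> dict:
        """block_id -> DataFrame of its rows, in pos_a order."""
        out = {}
        for bid, grp in self.records.groupby("block_id"):
            if len(grp) >= min_block_size:
                out[bid] = grp.sort_values("pos_a").reset_index(drop=True)
        return out


def read_homology_tables(
    paths: Iterable[str | Path],
    genomes: Mapping[str, Genome] | None = None,
) -> list[PairwiseHomologyTable]:
    """Read one table per file; optionally validate gene ids against genomes."""
    tables = []
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        try:
            df["pos_a"] = df["pos_a"].astype(int)
            df["pos_b"] = df["pos_b"].astype(int)
        except (KeyError, ValueError) as exc:
            raise HomologyTableError(f"{path}: malformed table: {exc}") from exc
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise HomologyTableError(f"{path}: missing columns {missing}")
        bad = df[df.isna().any(axis=1)]
        if len(bad):
            # +2: 1-based line numbers plus the header line
            raise HomologyTableError(
                f"{path}: malformed line {bad.index[0] + 2}"
            )
        if not len(df):
            raise HomologyTableError(f"{path}: empty table")
        ga, gb = df.iloc[0]["genome_a"], df.iloc[0]["genome_b"]
        if genomes is not None:
            for side, genome_name in (("a", ga), ("b", gb)):
                if genome_name not in genomes:
                    raise HomologyTableError(
                        f"{path}: unknown genome {genome_name!r}"
                    )
                known = genomes[genome_name].gene_ids()
                col = df[f"gene_{side}"]
                unknown = ~col.isin(known)
                if unknown.any():
                    row = df.index[unknown][0]
                    raise HomologyTableError(
                        f"{path}: line {row + 2}: unknown gene "
                        f"{col[row]!r} in genome {genome_name!r}"
                    )
        tables.append(PairwiseHomologyTable(ga, gb, df))
    return tables


def write_homology_table(table: PairwiseHomologyTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False, columns=COLUMNS)
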
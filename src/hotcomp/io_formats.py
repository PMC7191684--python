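"""Readers/writers for the on-disk formats used by the pipeline.

Internal coordinates are always 0-based half-open; GFF3 I/O shifts by one at
the boundary.  The LDhat-style rate dialect is whitespace-separated text with
a one-line header: per row a SNP position (kb by default) and the rate of the
interval to its right (per kb by default, zero on the final row).  Internal
rho is Morgans/bp everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo_trait import DriftTree
from .ratemap import PopulationMeta, RateMap, RateTrace

__all__ = [
    "FormatError",
    "GenomeLayout",
    "Interval",
    "GeneModel",
    "LdhatDialect",
    "read_ldhat_rates",
    "write_ldhat_rates",
    "read_rate_trace",
    "write_rate_trace",
    "read_bed",
    "write_bed",
    "read_gff_genes",
    "write_gff_genes",
    "read_newick_tree",
    "read_genome_layout",
    "write_genome_layout",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_population_meta",
    "write_population_meta",
]


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome name -> length in bp."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if int(length) < 1:
                raise FormatError(f"chromosome {name}: length must be >= 1")

    def __getitem__(self, chrom: str) -> int:
        return int(self.lengths[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths.values()))


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = field(default="", compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"{self.chrom}: negative start {self.start}")
        if self.start >= self.end:
            raise FormatError(
                f"{self.chrom}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Transcribed span with strand and exon structure (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        if self.start >= self.end:
            raise FormatError(f"{self.gene_id}: empty gene span")
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise FormatError(
                    f"{self.gene_id}: exon [{s},{e}) outside gene span "
                    f"[{self.start},{self.end})"
                )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons within the transcribed span."""
        exons = sorted(self.exons)
        out = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return tuple(out)


# ---------------------------------------------------------------------------
# LDhat-style rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdhatDialect:
    """Unit conventions of the rates text dialect.

    position_unit: 'kb' (LDhat convention) or 'bp'.
    rate_per: rates are rho per 'kb' (LDhat) or per 'bp'.
    """

    position_unit: str = "kb"
    rate_per: str = "kb"
    position_decimals: int = 3

    def __post_init__(self) -> None:
        if self.position_unit not in {"kb", "bp"}:
            raise ValueError("position_unit must be 'kb' or 'bp'")
        if self.rate_per not in {"kb", "bp"}:
            raise ValueError("rate_per must be 'kb' or 'bp'")


def read_ldhat_rates(
    path,
    dialect: LdhatDialect = LdhatDialect(),
    chrom: str = "chr1",
    population: str = "",
) -> RateMap:
    """Read an LDhat ``stats``-style rates file into a RateMap.

    n position rows yield n - 1 inter-SNP intervals; the rate printed on the
    final row (conventionally zero) is ignored.  Positions are converted to
    integer bp and rates to Morgans/bp.
    """
    path = Path(path)
    positions: list[float] = []
    rates: list[float] = []
    with path.open() as fh:
        lines = fh.readlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    body = lines[1:]  # header line
    for lineno, line in enumerate(body, start=2):
        parts = line.split()
        if not parts:
            continue
        try:
            pos = float(parts[0])
            rate = float(parts[1]) if len(parts) > 1 else 0.0
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparsable row: {line!r}") from exc
        if positions and pos <= positions[-1]:
            raise FormatError(
                f"{path}:{lineno}: position {pos} not greater than previous "
                f"{positions[-1]}"
            )
        positions.append(pos)
        rates.append(rate)
    if len(positions) < 2:
        raise FormatError(f"{path}: need at least 2 positions")
    pos_scale = 1000.0 if dialect.position_unit == "kb" else 1.0
    rate_scale = 1.0 / 1000.0 if dialect.rate_per == "kb" else 1.0
    bp = np.rint(np.asarray(positions) * pos_scale).astype(np.int64)
    rho = np.asarray(rates[:-1]) * rate_scale
    if np.any(rho < 0):
        bad = int(np.flatnonzero(rho < 0)[0]) + 2
        raise FormatError(f"{path}:{bad}: negative rate")
    return RateMap(chrom=chrom, positions=bp, rates=rho, population=population)


def write_ldhat_rates(
    ratemap: RateMap, path, dialect: LdhatDialect = LdhatDialect()
) -> None:
    """Inverse of :func:`read_ldhat_rates` (values kept to >= 6 sig. digits)."""
    path = Path(path)
    pos_scale = 1000.0 if dialect.position_unit == "kb" else 1.0
    rate_scale = 1000.0 if dialect.rate_per == "kb" else 1.0
    unit = dialect.position_unit
    with path.open("w") as fh:
        fh.write(f"Position({unit})\tMean_rho\n")
        rates = np.append(ratemap.rates * rate_scale, 0.0)
        for pos, rate in zip(ratemap.positions, rates):
            fh.write(
                f"{pos / pos_scale:.{dialect.position_decimals}f}\t{rate:.10g}\n"
            )


def read_rate_trace(path) -> RateTrace:
    """Read a trace TSV: one row per interval, one column per MCMC sample."""
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    return RateTrace(samples=arr)


def write_rate_trace(trace: RateTrace, path) -> None:
    np.savetxt(path, trace.samples, delimiter="\t", fmt="%.10g")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, layout: GenomeLayout | None = None) -> list[Interval]:
    """Read BED3+ (0-based half-open) into Intervals."""
    path = Path(path)
    out: list[Interval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = parts[3] if len(parts) > 3 else ""
            score = None
            if len(parts) > 4 and parts[4] not in {".", ""}:
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 and parts[5] in {"+", "-"} else None
            if layout is not None:
                if chrom not in layout:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom}")
                if end > layout[chrom]:
                    raise FormatError(
                        f"{path}:{lineno}: interval end {end} beyond "
                        f"{chrom} length {layout[chrom]}"
                    )
            out.append(Interval(chrom, start, end, name=name, score=score,
                                strand=strand))
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name or iv.score is not None or iv.strand is not None:
                cols.append(iv.name or ".")
            if iv.score is not None or iv.strand is not None:
                cols.append("%.6g" % iv.score if iv.score is not None else ".")
            if iv.strand is not None:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff_genes(path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GFF3 (1-based inclusive)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        start0 = gene.start - 1
        end0 = gene.end
        exons = []
        for exon in db.children(gene.id, featuretype="exon", order_by="start"):
            es, ee = exon.start - 1, exon.end
            if es < start0 or ee > end0:
                raise FormatError(
                    f"{gene.id}: exon [{es},{ee}) outside gene span "
                    f"[{start0},{end0})"
                )
            exons.append((es, ee))
        if not exons:
            exons = [(start0, end0)]
        strand = gene.strand if gene.strand in {"+", "-"} else "+"
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=start0,
                end=end0,
                strand=strand,
                exons=tuple(sorted(exons)),
            )
        )
    return genes


def write_gff_genes(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 gene + exon rows (shift to 1-based)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\thotcomp\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                fh.write(
                    f"{g.chrom}\thotcomp\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# newick / TSV tables
# ---------------------------------------------------------------------------

def read_newick_tree(path, expected_taxa: Iterable[str] | None = None) -> DriftTree:
    """Read a rooted newick drift tree; optionally validate the tip set."""
    text = Path(path).read_text()
    tree = DriftTree.from_newick(text)
    if expected_taxa is not None:
        expected = set(expected_taxa)
        got = set(tree.taxa)
        if expected != got:
            raise FormatError(
                f"tree tips {sorted(got)} do not match expected "
                f"{sorted(expected)}"
            )
    return tree


def read_genome_layout(path) -> GenomeLayout:
    """TSV with columns: chromosome, length."""
    lengths: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            name = parts[0]
            if name in lengths:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name}")
            lengths[name] = int(parts[1])
    return GenomeLayout(lengths)


def write_genome_layout(layout: GenomeLayout, path) -> None:
    with Path(path).open("w") as fh:
        for name, length in layout.lengths.items():
            fh.write(f"{name}\t{length}\n")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a labeled matrix TSV (row/col headers)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_population_meta(path) -> dict[str, PopulationMeta]:
    """TSV with columns: population, ne, inbreeding_f, sample_size."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "ne", "inbreeding_f", "sample_size"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["population"])] = PopulationMeta(
            name=str(row["population"]),
            ne=float(row["ne"]),
            inbreeding_f=float(row["inbreeding_f"]),
            sample_size=int(row["sample_size"]),
        )
    return out


def write_population_meta(meta: Mapping[str, PopulationMeta], path) -> None:
    rows = [
        {
            "population": m.name,
            "ne": m.ne,
            "inbreeding_f": m.inbreeding_f,
            "sample_size": m.sample_size,
        }
        for m in meta.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
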
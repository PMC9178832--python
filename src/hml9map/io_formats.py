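"""Domain types and readers/writers for the formats the pipeline touches.

All coordinates are 1-based inclusive internally (the convention of the
published element catalog; the ``length = end - start + 1`` invariant is
checked on every packaged row).  BED I/O converts to 0-based half-open at
the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

REGION_NAMES = ("LTR5", "gag", "pro", "pol", "env", "LTR3")
INTERNAL_REGIONS = ("gag", "pro", "pol", "env")

#: Region map of the Dfam LTR14C-HERVK14C-LTR14C proviral assembly
#: (5'LTR 1-587, gag 758-2548, pro 2548-3435, pol 3411-6060,
#: env 5975-8020, 3'LTR 8022-8608; total 8608 bp).
CANONICAL_REGIONS: dict[str, tuple[int, int]] = {
    "LTR5": (1, 587),
    "gag": (758, 2548),
    "pro": (2548, 3435),
    "pol": (3411, 6060),
    "env": (5975, 8020),
    "LTR3": (8022, 8608),
}

CANONICAL_REFERENCE_LENGTH = 8608

CONTEXT_CATEGORIES = ("Intergenic", "Intron", "Exon_intron", "Exonic_intergenic")


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class ProviralReference:
    """A proviral reference sequence with its ordered region coordinate map.

    Canonically the LTR5-gag-pro-pol-env-LTR3 layout of an endogenous
    retrovirus; ``pro`` and ``pol`` are allowed to overlap (ribosomal
    frameshift), as are ``pol`` and ``env``.
    """

    name: str
    sequence: str
    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(CANONICAL_REGIONS)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        missing = [r for r in REGION_NAMES if r not in self.regions]
        if missing:
            raise FormatError(f"region table is missing {missing}")
        n = len(self.sequence)
        for rname, (s, e) in self.regions.items():
            if not (1 <= s <= e <= n):
                raise FormatError(
                    f"region {rname} [{s},{e}] outside sequence [1,{n}]"
                )
        if self.regions["LTR5"][0] != 1:
            raise FormatError("LTR5 must start at position 1")
        starts = [self.regions[r][0] for r in REGION_NAMES]
        if starts != sorted(starts):
            raise FormatError("region starts must be non-decreasing")
        l5, l3 = self.region_length("LTR5"), self.region_length("LTR3")
        if abs(l5 - l3) / max(l5, l3) >= 0.05:
            raise FormatError(
                f"LTR5 ({l5} bp) and LTR3 ({l3} bp) lengths differ by >= 5%"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def region_length(self, name: str) -> int:
        s, e = self.regions[name]
        return e - s + 1

    def region_sequence(self, name: str) -> str:
        s, e = self.regions[name]
        return self.sequence[s - 1 : e]

    @property
    def ltr_length(self) -> int:
        return self.region_length("LTR5")

    def region_of(self, position: int) -> list[str]:
        """Region name(s) containing a 1-based reference position."""
        return [r for r, (s, e) in self.regions.items() if s <= position <= e]

    def is_ltr_position(self, position: int) -> bool:
        for r in ("LTR5", "LTR3"):
            s, e = self.regions[r]
            if s <= position <= e:
                return True
        return False


@dataclass
class GenomeAssembly:
    """A genome as an ordered chromosome -> sequence map.

    Ungapped length excludes N runs, mirroring assembly gap accounting.
    """

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        self.chromosomes = {c: s.upper() for c, s in self.chromosomes.items()}

    def ungapped_length(self, chrom: str) -> int:
        seq = self.chromosomes[chrom]
        return len(seq) - seq.count("N")

    @property
    def ungapped_lengths(self) -> dict[str, int]:
        return {c: self.ungapped_length(c) for c in self.chromosomes}

    @property
    def total_ungapped_length(self) -> int:
        return sum(self.ungapped_lengths.values())

    def __len__(self) -> int:
        return len(self.chromosomes)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAssembly":
        chroms = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
        }
        if not chroms:
            raise FormatError(f"no FASTA records in {path}")
        return cls(chroms)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.chromosomes.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, span, and sorted non-overlapping exons."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: exon [{s},{e}] outside span"
                )
            if prev_end is not None and s <= prev_end:
                raise FormatError(
                    f"gene {self.gene_id}: exons unsorted or overlapping"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)


@dataclass
class ElementTableRow:
    """One row of an element report table (published-catalog column semantics)."""

    locus: str
    chrom: str
    strand: str
    start: int
    end: int
    length: int
    coverage_pct: float
    qgap_pct: float
    context: str
    gene: str = "NA"

    def __post_init__(self) -> None:
        if self.length != self.end - self.start + 1:
            raise FormatError(
                f"{self.locus}: length {self.length} != "
                f"{self.end} - {self.start} + 1"
            )


# ---------------------------------------------------------------------------
# Reference loading
# ---------------------------------------------------------------------------

def read_region_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a region table: ``region_name<TAB>start<TAB>end`` per line."""
    regions: dict[str, tuple[int, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"bad region line: {line!r}")
        regions[parts[0]] = (int(parts[1]), int(parts[2]))
    return regions


def write_region_table(
    regions: Mapping[str, tuple[int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, (s, e) in regions.items():
            fh.write(f"{name}\t{s}\t{e}\n")


def load_reference(
    fasta_path: str | Path, region_table_path: str | Path
) -> ProviralReference:
    """Load a single-record reference FASTA with its region table."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise FormatError(
            f"reference FASTA must have exactly one record, got {len(records)}"
        )
    regions = read_region_table(region_table_path)
    return ProviralReference(
        name=records[0].id, sequence=str(records[0].seq), regions=regions
    )


# ---------------------------------------------------------------------------
# Packaged catalog tables (published HML-9 element catalog transcriptions)
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("hml9map.data").joinpath(name).read_text()


def load_catalog() -> dict[str, pd.DataFrame]:
    """Load the packaged HML-9 catalog tables.

    Returns a dict with keys ``proviruses`` (23 rows), ``solo_ltrs``
    (47 rows), ``integrity`` (per-region integrity, 23 rows) and
    ``dating`` (20 rows of divergences and ages).  Every provirus and
    solo-LTR row is validated against the length invariant.
    """
    tables = {
        "proviruses": pd.read_csv(
            io.StringIO(_data_text("hml9_proviruses.tsv")), sep="\t"
        ),
        "solo_ltrs": pd.read_csv(
            io.StringIO(_data_text("hml9_solo_ltrs.tsv")), sep="\t"
        ),
        "integrity": pd.read_csv(
            io.StringIO(_data_text("hml9_integrity.tsv")), sep="\t"
        ),
        "dating": pd.read_csv(
            io.StringIO(_data_text("hml9_dating.tsv")), sep="\t",
            na_values=["NA"],
        ),
    }
    for key in ("proviruses", "solo_ltrs"):
        df = tables[key]
        bad = df[df.length_bp != df.end - df.start + 1]
        if len(bad):
            raise FormatError(
                f"catalog table {key}: length invariant violated at "
                f"{bad.locus.tolist()}"
            )
    return tables


def catalog_rows(df: pd.DataFrame) -> list[ElementTableRow]:
    """Convert a catalog DataFrame to validated ElementTableRow objects."""
    rows = []
    for rec in df.itertuples():
        rows.append(
            ElementTableRow(
                locus=rec.locus,
                chrom=rec.chrom,
                strand=rec.strand,
                start=int(rec.start),
                end=int(rec.end),
                length=int(rec.length_bp),
                coverage_pct=float(rec.coverage_pct),
                qgap_pct=float(rec.qgap_pct),
                context=rec.context,
                gene=str(rec.gene),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Gene annotation (GFF3)
# ---------------------------------------------------------------------------

def read_gene_annotation(gff3_path: str | Path) -> list[GeneModel]:
    """Read gene/exon features from a GFF3 file into GeneModel objects.

    Exons are attached to genes via their ``Parent`` attribute chain
    (gene <- mRNA <- exon, or exon directly on the gene).
    """
    import gffutils

    text = Path(gff3_path).read_text()
    if not any(
        line and not line.startswith("#") for line in text.splitlines()
    ):
        return []
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            if exon.start < gene.start or exon.end > gene.end:
                raise FormatError(
                    f"exon [{exon.start},{exon.end}] outside gene "
                    f"{gene.id} span [{gene.start},{gene.end}]"
                )
            exons.append((exon.start, exon.end))
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=tuple(exons),
            )
        )
    return genes


def write_gene_annotation(
    genes: Iterable[GeneModel], path: str | Path
) -> None:
    """Write GeneModels as a minimal GFF3 (gene + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\thml9map\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\thml9map\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BED / cytobands
# ---------------------------------------------------------------------------

def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return bed_start + 1, bed_end


def read_cytobands(path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED-like cytoband table (chrom, start, end, band name).

    Band labels are stored as e.g. ``16p12.3`` (chromosome shorthand taken
    from the chrom column with any ``chr`` prefix stripped, prepended to the
    band name when the band name does not already include it).
    """
    trees: dict[str, IntervalTree] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        chrom, s, e, band = line.split("\t")[:4]
        short = chrom[3:] if chrom.startswith("chr") else chrom
        label = band if band.startswith(short) else short + band
        start1, end1 = from_bed_interval(int(s), int(e))
        trees.setdefault(chrom, IntervalTree()).addi(start1, end1 + 1, label)
    return trees


# ---------------------------------------------------------------------------
# Element tables
# ---------------------------------------------------------------------------

ELEMENT_TABLE_COLUMNS = [
    "locus",
    "chrom",
    "strand",
    "start",
    "end",
    "length",
    "coverage_pct",
    "qgap_pct",
    "context",
    "gene",
]


def write_element_table(
    rows: Sequence[ElementTableRow], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {c: getattr(r, c) for c in ELEMENT_TABLE_COLUMNS}
            for r in rows
        ],
        columns=ELEMENT_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_element_table(path: str | Path) -> list[ElementTableRow]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        ElementTableRow(
            locus=str(rec.locus),
            chrom=str(rec.chrom),
            strand=str(rec.strand),
            start=int(rec.start),
            end=int(rec.end),
            length=int(rec.length),
            coverage_pct=float(rec.coverage_pct),
            qgap_pct=float(rec.qgap_pct),
            context=str(rec.context),
            gene=str(rec.gene),
        )
        for rec in df.itertuples()
    ]
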
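"""Seeded synthetic genomes with planted ERV elements and known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a provirus integrates with two *identical* LTRs which then diverge
independently under a neutral clock, internal regions diverge at the same
per-site rate, solo LTRs are single LTR copies, and optional deletions
remove reference intervals.  Planted elements *replace* a same-length window
of background sequence (target-site replacement), so gene and element
coordinates need no shifting and every planted interval is exact ground
truth.

Substitutions follow a Kimura two-parameter kernel (transition:transversion
rate ratio kappa, default 2), matching the distance model offered
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import (
    CANONICAL_REGIONS,
    GeneModel,
    GenomeAssembly,
    ProviralReference,
    write_gene_annotation,
    write_region_table,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Neutral substitution rate used as the molecular clock,
#: in substitutions/site/million years (0.2%/nt/my).
DEFAULT_RATE_PER_MY = 0.002


class SaturationError(ValueError):
    """Divergence target too high for a meaningful substitution process."""


class CapacityError(ValueError):
    """Requested plants or genes do not fit in the genome."""


class OverlapError(ValueError):
    """A planted element would overlap another planted element."""


@dataclass(frozen=True)
class MutationModel:
    """Per-site substitution process parameters."""

    per_site_rate: float = DEFAULT_RATE_PER_MY
    kappa: float = 2.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.per_site_rate < 0:
            raise ValueError("per_site_rate must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


@dataclass(frozen=True)
class PlantSpec:
    """Specification of one element to plant."""

    kind: str  # full_provirus | deleted_provirus | solo_LTR
    chrom: str
    strand: str = "+"
    insert_pos: Optional[int] = None  # 1-based start; None -> auto-placed
    true_age_my: float = 0.0
    deletions: tuple[tuple[int, int], ...] = ()
    context_target: Optional[str] = None  # intergenic | intron | exon | None

    def __post_init__(self) -> None:
        if self.kind not in ("full_provirus", "deleted_provirus", "solo_LTR"):
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if self.true_age_my < 0:
            raise ValueError("true_age_my must be >= 0")
        ivs = sorted(self.deletions)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError("deletion intervals overlap")


@dataclass
class TruthRecord:
    """Realized placement of one planted element."""

    element_id: str
    kind: str
    chrom: str
    start: int
    end: int
    strand: str
    true_age_my: float
    deletions: tuple[tuple[int, int], ...]
    context: str  # expected genomic-context category
    substitutions: int  # realized substitution count over the element


@dataclass
class SyntheticTruth:
    """Ledger of all planted elements for parameter-recovery tests."""

    records: list[TruthRecord] = field(default_factory=list)
    rng_seed: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "element_id\tkind\tchrom\tstart\tend\tstrand\t"
                "true_age_my\tdeletions\tcontext\tsubstitutions\n"
            )
            for r in self.records:
                dels = ";".join(f"{s}-{e}" for s, e in r.deletions) or "NA"
                fh.write(
                    f"{r.element_id}\t{r.kind}\t{r.chrom}\t{r.start}\t"
                    f"{r.end}\t{r.strand}\t{r.true_age_my}\t{dels}\t"
                    f"{r.context}\t{r.substitutions}\n"
                )


# ---------------------------------------------------------------------------
# Sequence-level operations
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform ACGT background sequence."""
    return "".join(rng.choice(list(BASES), size=length))


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def mutate_sequence(
    seq: str,
    divergence_target: float,
    model: MutationModel = MutationModel(),
    seed: int | np.random.Generator = 0,
) -> str:
    """Substitute each site with probability ``divergence_target``.

    Given a substitution, a transition occurs with probability
    kappa/(kappa+2) and each transversion with probability 1/(kappa+2).
    Ambiguous bases are left untouched.  Deterministic for a fixed seed.
    """
    if not 0 <= divergence_target < 0.75:
        raise SaturationError(
            f"divergence_target {divergence_target} outside [0, 0.75)"
        )
    if divergence_target == 0 or not seq:
        return seq
    rng = _as_rng(seed)
    n = len(seq)
    hit = rng.random(n) < divergence_target
    kind = rng.random(n)  # substitution type draw, consumed for all sites
    p_ts = model.kappa / (model.kappa + 2.0)
    out = list(seq)
    for i in np.nonzero(hit)[0]:
        base = out[i]
        if base not in _BASE_INDEX:
            continue
        u = kind[i]
        if u < p_ts:
            out[i] = _TRANSITION[base]
        else:
            # two transversion partners, equally likely
            tv = [b for b in BASES if b != base and b != _TRANSITION[base]]
            out[i] = tv[0] if u < p_ts + (1 - p_ts) / 2 else tv[1]
    return "".join(out)


def count_differences(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _ancestral_provirus(reference: ProviralReference) -> tuple[str, str, str]:
    """Split the reference into (LTR copy, internal, LTR copy).

    At integration both LTRs are identical; the ancestral provirus is the
    reference with its 3'LTR replaced by a copy of the 5'LTR.  Requires
    equal LTR lengths so reference coordinates carry over unchanged.
    """
    l5s, l5e = reference.regions["LTR5"]
    l3s, l3e = reference.regions["LTR3"]
    if (l5e - l5s) != (l3e - l3s):
        raise ValueError("ancestral planting requires equal LTR lengths")
    ltr = reference.sequence[l5s - 1 : l5e]
    internal = reference.sequence[l5e:l3s - 1]
    return ltr, internal, ltr


def build_element(
    reference: ProviralReference,
    spec: PlantSpec,
    model: MutationModel,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Realize one element sequence (plus its substitution count).

    For proviruses the two LTR copies are mutated independently from the
    same ancestral LTR, so the expected LTR-LTR p-distance is about
    2 x rate x age.  Deletions (reference coordinates) are applied after
    mutation.  Minus-strand elements are reverse-complemented.
    """
    d = model.per_site_rate * spec.true_age_my
    if spec.kind == "solo_LTR":
        anc = reference.region_sequence("LTR5")
        mutated = mutate_sequence(anc, d, model, rng)
        subs = count_differences(anc, mutated)
        element = mutated
    else:
        ltr, internal, _ = _ancestral_provirus(reference)
        m5 = mutate_sequence(ltr, d, model, rng)
        mi = mutate_sequence(internal, d, model, rng)
        m3 = mutate_sequence(ltr, d, model, rng)
        subs = (
            count_differences(ltr, m5)
            + count_differences(internal, mi)
            + count_differences(ltr, m3)
        )
        element = m5 + mi + m3
        if spec.deletions:
            keep = np.ones(len(element), dtype=bool)
            for s, e in spec.deletions:
                if not (1 <= s <= e <= len(element)):
                    raise ValueError(
                        f"deletion [{s},{e}] outside reference length "
                        f"{len(element)}"
                    )
                keep[s - 1 : e] = False
            element = "".join(c for c, k in zip(element, keep) if k)
    if spec.strand == "-":
        element = reverse_complement(element)
    return element, subs


def plant_element(
    genome: GenomeAssembly,
    reference: ProviralReference,
    spec: PlantSpec,
    model: MutationModel = MutationModel(),
    seed: int | np.random.Generator = 0,
    existing: Sequence[TruthRecord] = (),
    element_id: str = "plant1",
) -> tuple[GenomeAssembly, TruthRecord]:
    """Plant one element by replacing a same-length genomic window."""
    rng = _as_rng(seed)
    element, subs = build_element(reference, spec, model, rng)
    if spec.insert_pos is None:
        raise ValueError("plant_element requires an explicit insert_pos")
    chrom_seq = genome.chromosomes[spec.chrom]
    start = spec.insert_pos
    end = start + len(element) - 1
    if not (1 <= start and end <= len(chrom_seq)):
        raise CapacityError(
            f"element [{start},{end}] does not fit chromosome "
            f"{spec.chrom} of length {len(chrom_seq)}"
        )
    for r in existing:
        if r.chrom == spec.chrom and not (end < r.start or start > r.end):
            raise OverlapError(
                f"element [{start},{end}] overlaps {r.element_id}"
            )
    new_seq = chrom_seq[: start - 1] + element + chrom_seq[end:]
    chroms = dict(genome.chromosomes)
    chroms[spec.chrom] = new_seq
    record = TruthRecord(
        element_id=element_id,
        kind=spec.kind,
        chrom=spec.chrom,
        start=start,
        end=end,
        strand=spec.strand,
        true_age_my=spec.true_age_my,
        deletions=spec.deletions,
        context=spec.context_target or "free",
        substitutions=subs,
    )
    return GenomeAssembly(chroms), record


# ---------------------------------------------------------------------------
# Whole-genome generation
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    """Configuration for a synthetic genome."""

    chromosomes: dict[str, int]
    n_genes: int = 0
    gene_length: int = 9000
    exon_length: int = 300
    n_exons: int = 3
    plants: tuple[PlantSpec, ...] = ()
    intergenic_margin: int = 200
    #: minimum spacing between planted elements; kept above the default
    #: locus-merge gap so distinct plants never fuse into one locus
    plant_margin: int = 12000


def _make_gene(
    gene_id: str, chrom: str, start: int, strand: str, cfg: GenomeConfig
) -> GeneModel:
    end = start + cfg.gene_length - 1
    # exons evenly spread across the span, first at the start, last at the end
    gaps = cfg.n_exons - 1
    exons = []
    for i in range(cfg.n_exons):
        if gaps:
            off = round(i * (cfg.gene_length - cfg.exon_length) / gaps)
        else:
            off = 0
        s = start + off
        exons.append((s, s + cfg.exon_length - 1))
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        exons=tuple(exons),
    )


def _place_genes(
    cfg: GenomeConfig, rng: np.random.Generator
) -> list[GeneModel]:
    genes: list[GeneModel] = []
    if cfg.n_genes == 0:
        return genes
    chrom_ids = list(cfg.chromosomes)
    counter = 0
    attempts = 0
    while counter < cfg.n_genes:
        attempts += 1
        if attempts > cfg.n_genes * 200:
            raise CapacityError("could not place requested genes")
        chrom = chrom_ids[int(rng.integers(len(chrom_ids)))]
        clen = cfg.chromosomes[chrom]
        if clen < cfg.gene_length + 2 * cfg.intergenic_margin:
            continue
        start = int(
            rng.integers(
                cfg.intergenic_margin + 1,
                clen - cfg.gene_length - cfg.intergenic_margin,
            )
        )
        end = start + cfg.gene_length - 1
        clash = any(
            g.chrom == chrom
            and not (
                end + cfg.intergenic_margin < g.start
                or start - cfg.intergenic_margin > g.end
            )
            for g in genes
        )
        if clash:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        counter += 1
        genes.append(_make_gene(f"gene{counter}", chrom, start, strand, cfg))
    return genes


def _element_length(reference: ProviralReference, spec: PlantSpec) -> int:
    if spec.kind == "solo_LTR":
        return reference.region_length("LTR5")
    n = len(reference)
    return n - sum(e - s + 1 for s, e in spec.deletions)


def _candidate_ok(
    start: int,
    end: int,
    chrom: str,
    target: Optional[str],
    genes: Sequence[GeneModel],
    placed: Sequence[TruthRecord],
    gene_margin: int,
    plant_margin: int,
) -> Optional[str]:
    """Return the realized context category if the window is acceptable."""
    for r in placed:
        if r.chrom == chrom and not (
            end < r.start - plant_margin or start > r.end + plant_margin
        ):
            return None
    overlapping = [
        g for g in genes if g.chrom == chrom and not (end < g.start or start > g.end)
    ]
    if target in (None, "free"):
        pass
    if target == "intergenic":
        near = any(
            g.chrom == chrom
            and not (end < g.start - gene_margin or start > g.end + gene_margin)
            for g in genes
        )
        return "Intergenic" if not near else None
    if target == "intron":
        for g in overlapping:
            for s, e in g.introns:
                if s <= start and end <= e:
                    return "Intron"
        return None
    if target == "exon":
        # must straddle an exon-intron junction while staying inside the gene
        for g in overlapping:
            if not (g.start <= start and end <= g.end):
                continue
            hits_exon = any(not (end < s or start > e) for s, e in g.exons)
            hits_intron = any(
                not (end < s or start > e) for s, e in g.introns
            )
            if hits_exon and hits_intron:
                return "Exon_intron"
        return None
    # free placement: report what we got
    if not overlapping:
        return "Intergenic"
    g = overlapping[0]
    inside = g.start <= start and end <= g.end
    hits_exon = any(not (end < s or start > e) for s, e in g.exons)
    if not inside:
        return "Exonic_intergenic" if hits_exon else "Intergenic"
    return "Exon_intron" if hits_exon else "Intron"


def generate_genome(
    config: GenomeConfig,
    seed: int,
    reference: Optional[ProviralReference] = None,
    model: MutationModel = MutationModel(),
    out_dir: Optional[str | Path] = None,
) -> tuple[GenomeAssembly, list[GeneModel], SyntheticTruth, ProviralReference]:
    """Generate a genome with genes and planted elements; fully deterministic.

    When ``out_dir`` is given, writes ``genome.fasta``, ``genes.gff3``,
    ``truth.tsv``, ``reference.fasta`` and ``reference.regions.tsv``.
    """
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = make_reference(int(rng.integers(2**31)))
    chroms = {
        cid: random_sequence(length, rng)
        for cid, length in config.chromosomes.items()
    }
    genome = GenomeAssembly(chroms)
    genes = _place_genes(config, rng)
    truth = SyntheticTruth(rng_seed=seed)
    for i, spec in enumerate(config.plants, 1):
        length = _element_length(reference, spec)
        clen = config.chromosomes[spec.chrom]
        if length > clen:
            raise CapacityError(
                f"element of {length} bp exceeds chromosome {spec.chrom}"
            )
        if spec.insert_pos is not None:
            start = spec.insert_pos
            ctx = _candidate_ok(
                start,
                start + length - 1,
                spec.chrom,
                spec.context_target,
                genes,
                truth.records,
                config.intergenic_margin,
                config.plant_margin,
            )
            if ctx is None:
                raise OverlapError(
                    f"explicit position {start} on {spec.chrom} conflicts "
                    "with genes/plants or misses the requested context"
                )
            placed_spec = spec
        else:
            ctx = None
            start = None
            for _ in range(2000):
                cand = int(rng.integers(1, clen - length + 1))
                ctx = _candidate_ok(
                    cand,
                    cand + length - 1,
                    spec.chrom,
                    spec.context_target,
                    genes,
                    truth.records,
                    config.intergenic_margin,
                    config.plant_margin,
                )
                if ctx is not None:
                    start = cand
                    break
            if start is None:
                raise CapacityError(
                    f"could not place plant {i} ({spec.kind}, "
                    f"context={spec.context_target}) on {spec.chrom}"
                )
            placed_spec = replace(spec, insert_pos=start)
        genome, record = plant_element(
            genome,
            reference,
            placed_spec,
            model,
            rng,
            existing=truth.records,
            element_id=f"plant{i}",
        )
        record.context = ctx
        truth.records.append(record)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(out / "genome.fasta")
        write_gene_annotation(genes, out / "genes.gff3")
        truth.to_tsv(out / "truth.tsv")
        with open(out / "reference.fasta", "w") as fh:
            fh.write(f">{reference.name}\n")
            for j in range(0, len(reference.sequence), 70):
                fh.write(reference.sequence[j : j + 70] + "\n")
        write_region_table(reference.regions, out / "reference.regions.tsv")
    return genome, genes, truth, reference


# ---------------------------------------------------------------------------
# Synthetic reference and tRNA library
# ---------------------------------------------------------------------------

#: 3-letter amino-acid codes used for synthetic tRNA identifiers.
TRNA_AMINO_ACIDS = ("Lys", "Arg", "Gly", "His", "Leu", "Phe", "Ser", "Trp")


def make_trna_library(
    seed: int, amino_acids: Sequence[str] = TRNA_AMINO_ACIDS, length: int = 76
) -> list[tuple[str, str]]:
    """Synthetic tRNA library with ids encoding the amino-acid type."""
    rng = np.random.default_rng(seed)
    return [
        (f"tRNA-{aa}-1-1", random_sequence(length, rng))
        for aa in amino_acids
    ]


def write_trna_fasta(
    library: Sequence[tuple[str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, seq in library:
            fh.write(f">{name}\n{seq}\n")


def make_reference(
    seed: int,
    trna_lib: Optional[Sequence[tuple[str, str]]] = None,
    pbs_trna: str = "Lys",
    pbs_offset: int = 3,
    pbs_len: int = 18,
) -> ProviralReference:
    """Synthetic stand-in for a proviral reference assembly.

    A random 8,608 bp sequence with the canonical region map, whose 3'LTR is
    an exact copy of the 5'LTR (an age-zero element).  When a tRNA library
    is supplied, a PBS complementary to the 3' end of the ``pbs_trna`` tRNA
    is written ``pbs_offset`` nt downstream of the 5'LTR.
    """
    rng = np.random.default_rng(seed)
    n = CANONICAL_REGIONS["LTR3"][1]
    seq = list(random_sequence(n, rng))
    l5s, l5e = CANONICAL_REGIONS["LTR5"]
    l3s, l3e = CANONICAL_REGIONS["LTR3"]
    seq[l3s - 1 : l3e] = seq[l5s - 1 : l5e]
    if trna_lib is not None:
        match = [s for name, s in trna_lib if pbs_trna in name]
        if not match:
            raise ValueError(f"no {pbs_trna} tRNA in library")
        pbs = reverse_complement(match[0][-pbs_len:])
        start = l5e + pbs_offset  # 1-based start of the PBS
        seq[start - 1 : start - 1 + pbs_len] = pbs
    return ProviralReference(
        name="synthetic-HML9-reference", sequence="".join(seq)
    )
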
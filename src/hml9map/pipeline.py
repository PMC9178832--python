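"""End-to-end orchestration: discover -> annotate -> date -> landscape ->
regulate -> pbs, plus replay of the packaged catalog summaries.

All stages run from a single config with one seed; outputs are plain TSV
report tables whose columns mirror the published catalog semantics, and a
JSON run report with per-stage row counts and the parameters applied.
Rerunning the same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import dating, discovery, landscape, motifs, regulatory, structure
from .io_formats import (
    GenomeAssembly,
    ProviralReference,
    load_catalog,
    load_reference,
    read_cytobands,
    read_gene_annotation,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed for one pipeline run."""

    genome: str
    reference: str
    regions: str
    out_dir: str
    genes: Optional[str] = None
    cytobands: Optional[str] = None
    pwms: Optional[str] = None
    trna_lib: Optional[str] = None
    categories: Optional[str] = None
    solo_screen_pct: float = 90.0
    provirus_screen_pct: float = 80.0
    region_screen_pct: float = 90.0
    ltr_presence_pct: float = 50.0
    pwm_threshold: float = 0.95
    merge_gap: int = 10000
    clock_rate_pct: float = dating.CLOCK_RATE_PCT_PER_MY
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def validate(self) -> None:
        for attr in ("genome", "reference", "regions"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {attr}={p} does not exist")
        for attr in ("genes", "cytobands", "pwms", "trna_lib", "categories"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {attr}={p} does not exist")


@dataclass
class RunReport:
    stage_counts: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    filters: list[str] = field(default_factory=list)


def _locus_to_row(locus: discovery.ElementLocus) -> dict:
    return {
        "locus": locus.name or locus.locus_id,
        "chrom": locus.chrom,
        "strand": locus.strand,
        "start": locus.start,
        "end": locus.end,
        "length": locus.length,
        "class": locus.element_class,
        "coverage_pct": round(locus.coverage_pct, 2),
        "qgap_pct": round(locus.qgap_pct, 2),
    }


def run_all(config: PipelineConfig) -> RunReport:
    """Run every stage over the configured inputs; write report tables."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=asdict(config))
    reference = load_reference(config.reference, config.regions)
    genome = GenomeAssembly.from_fasta(config.genome)
    genes = read_gene_annotation(config.genes) if config.genes else []
    cytobands = read_cytobands(config.cytobands) if config.cytobands else None

    # --- discovery ---------------------------------------------------------
    index = discovery.build_index(genome)
    chains = discovery.search(reference, index, genome)
    loci = discovery.merge_chains_to_loci(
        chains, reference, max_locus_gap=config.merge_gap
    )
    discovery.name_loci(loci, cytobands)
    report.stage_counts["chains"] = len(chains)
    report.stage_counts["loci"] = len(loci)
    elements_df = pd.DataFrame([_locus_to_row(l) for l in loci])
    elements_df.to_csv(out / "elements.tsv", sep="\t", index=False)

    # --- structural annotation --------------------------------------------
    alignments: dict[str, structure.PairwiseAlignment] = {}
    integrity_rows = []
    region_seqs: dict[str, dict[str, str]] = {}
    for locus in loci:
        seq = genome.chromosomes[locus.chrom][locus.start - 1 : locus.end]
        if locus.strand == "-":
            from .synthetic import reverse_complement

            seq = reverse_complement(seq)
        aln = structure.align_to_reference(seq, reference)
        alignments[locus.locus_id] = aln
        integ, _ = structure.annotate_regions(
            aln, reference.regions, locus_id=locus.locus_id
        )
        integrity_rows.append(
            {"locus": locus.name or locus.locus_id, "locus_id": locus.locus_id}
            | {r: round(v, 2) for r, v in integ.integrity.items()}
        )
        region_seqs[locus.locus_id] = structure.extract_region_sequences(
            aln, reference.regions
        )
    integrity_df = pd.DataFrame(integrity_rows)
    integrity_df.to_csv(out / "integrity.tsv", sep="\t", index=False)
    report.stage_counts["annotated"] = len(integrity_rows)

    # --- dating ------------------------------------------------------------
    integrity_by_id = {r["locus_id"]: r for r in integrity_rows}
    provirus_ids = [
        l.locus_id for l in loci if l.element_class == "provirus"
    ]
    region_Ds: dict[str, dict[str, Optional[float]]] = {
        lid: {} for lid in provirus_ids
    }
    for region in ("gag", "pro", "pol", "env"):
        eligible = [
            lid
            for lid in provirus_ids
            if integrity_by_id[lid].get(region, 0) > config.region_screen_pct
        ]
        report.filters.append(
            f"region {region}: {len(eligible)}/{len(provirus_ids)} pass "
            f">{config.region_screen_pct}% integrity screen"
        )
        if len(eligible) < 2:
            continue
        aligned = [region_seqs[lid][region] for lid in eligible]
        consensus = dating.build_consensus(
            aligned, reference=reference.region_sequence(region)
        )
        for lid in eligible:
            try:
                res = dating.p_distance(region_seqs[lid][region], consensus)
                region_Ds[lid][region] = res.D
            except dating.UndefinedDistanceError:
                region_Ds[lid][region] = None
    dating_rows = []
    for locus in loci:
        if locus.locus_id not in region_Ds:
            continue
        ds = region_Ds[locus.locus_id]
        mean_d, age_int = dating.date_internal(
            ds, rate_pct=config.clock_rate_pct
        )
        row_int = integrity_by_id[locus.locus_id]
        if (
            row_int.get("LTR5", 0) >= config.ltr_presence_pct
            and row_int.get("LTR3", 0) >= config.ltr_presence_pct
        ):
            d_ltr, age_ltr = dating.date_ltr_pair(
                region_seqs[locus.locus_id]["LTR5"],
                region_seqs[locus.locus_id]["LTR3"],
                rate_pct=config.clock_rate_pct,
            )
        else:
            d_ltr, age_ltr = None, None
        dating_rows.append(
            {
                "locus": locus.name or locus.locus_id,
                "locus_id": locus.locus_id,
                **{
                    f"d_{r}": (round(ds[r], 5) if ds.get(r) is not None else "NA")
                    for r in ("gag", "pro", "pol", "env")
                },
                "mean_d": round(mean_d, 6) if mean_d is not None else "NA",
                "age_internal_my": (
                    round(age_int, 2) if age_int is not None else "NA"
                ),
                "d_ltr": round(d_ltr, 5) if d_ltr is not None else "NA",
                "age_ltr_my": round(age_ltr, 2) if age_ltr is not None else "NA",
            }
        )
    pd.DataFrame(dating_rows).to_csv(out / "dating.tsv", sep="\t", index=False)
    report.stage_counts["dated"] = len(dating_rows)

    # --- chromosomal distribution and genomic context ----------------------
    observed: dict[str, int] = {}
    for locus in loci:
        observed[locus.chrom] = observed.get(locus.chrom, 0) + 1
    dist = landscape.distribution_test(observed, genome.ungapped_lengths)
    dist.table.to_csv(out / "distribution.tsv", sep="\t", index=False)
    with open(out / "distribution_summary.json", "w") as fh:
        json.dump(
            {"chi2": dist.chi2, "df": dist.df, "p_value": dist.p_value}, fh,
            indent=1,
        )
    contexts = [
        landscape.classify_context(
            l.locus_id, l.chrom, l.start, l.end, l.strand, genes
        )
        for l in loci
    ]
    ctx_df = pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "category": c.category,
                "genes": ";".join(c.gene_ids) or "NA",
                "orientation": c.orientation_relation,
            }
            for c in contexts
        ]
    )
    ctx_df.to_csv(out / "context.tsv", sep="\t", index=False)
    landscape.summarize_context([c.category for c in contexts]).to_csv(
        out / "context_summary.tsv", sep="\t", index=False
    )
    report.stage_counts["contexts"] = len(contexts)

    # --- regulatory domains and association --------------------------------
    if genes:
        chrom_lengths = {c: len(s) for c, s in genome.chromosomes.items()}
        domains = regulatory.build_domains(genes, chrom_lengths)
        element_map = {
            l.locus_id: (l.chrom, l.start, l.end) for l in loci
        }
        associations, counts = regulatory.associate(element_map, domains)
        pd.DataFrame(
            [
                {
                    "element": a.element_id,
                    "gene": a.gene_id,
                    "distance": a.distance,
                    "bin": a.bin,
                }
                for a in associations
            ]
        ).to_csv(out / "associations.tsv", sep="\t", index=False)
        bins = regulatory.bin_distances(associations)
        pd.DataFrame(
            [{"bin": k, "count": v} for k, v in bins.items()]
        ).to_csv(out / "distance_bins.tsv", sep="\t", index=False)
        report.stage_counts["associations"] = len(associations)
        if config.categories:
            cat_df = pd.read_csv(config.categories, sep="\t")
            cats: dict[str, set[str]] = {}
            for rec in cat_df.itertuples():
                cats.setdefault(rec.category_id, set()).add(rec.gene_id)
            universe = [g.gene_id for g in genes]
            gene_list = sorted({a.gene_id for a in associations})
            if gene_list:
                results = regulatory.ora(gene_list, cats, universe)
                pd.DataFrame(
                    [
                        {
                            "category": r.category_id,
                            "K": r.K,
                            "n": r.n,
                            "k": r.k,
                            "ratio": round(r.enrichment_ratio, 4),
                            "p": r.p_value,
                            "fdr": r.fdr,
                        }
                        for r in results
                    ]
                ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
                report.stage_counts["enriched_categories"] = len(results)

    # --- motifs and PBS -----------------------------------------------------
    if config.pwms:
        pwms = motifs.PWM.from_jaspar(config.pwms)
        hit_rows = []
        ltr_seq = reference.region_sequence("LTR5")
        for pwm in pwms:
            for h in motifs.scan(pwm, ltr_seq, threshold=config.pwm_threshold):
                hit_rows.append(
                    {
                        "matrix": h.matrix_id,
                        "position": h.position,
                        "strand": h.strand,
                        "score": round(h.score, 4),
                        "relative_score": round(h.relative_score, 4),
                    }
                )
        pd.DataFrame(hit_rows).to_csv(out / "tfbs.tsv", sep="\t", index=False)
        report.stage_counts["tfbs_hits"] = len(hit_rows)
    if config.trna_lib:
        from Bio import SeqIO

        lib = [
            (rec.id, str(rec.seq))
            for rec in SeqIO.parse(config.trna_lib, "fasta")
        ]
        pbs_rows = []
        pbs_seqs = []
        for locus in loci:
            if locus.element_class != "provirus":
                continue
            if integrity_by_id[locus.locus_id].get("LTR5", 0) <= (
                config.provirus_screen_pct
            ):
                continue
            aln = alignments[locus.locus_id]
            ltr5_end_elem = _element_coordinate(
                aln, reference.regions["LTR5"][1]
            )
            if ltr5_end_elem is None:
                continue
            call = motifs.extract_pbs(
                aln.element_sequence,
                ltr5_end_elem,
                lib,
                locus_id=locus.locus_id,
            )
            pbs_rows.append(
                {
                    "locus_id": call.locus_id,
                    "found": call.found,
                    "pbs": call.pbs_seq,
                    "offset": call.offset,
                    "trna": call.trna_id,
                    "type": call.trna_type,
                    "identity": round(call.identity, 4),
                }
            )
            if call.found:
                pbs_seqs.append(call.pbs_seq)
        pd.DataFrame(pbs_rows).to_csv(out / "pbs.tsv", sep="\t", index=False)
        if len(pbs_seqs) >= 1:
            profile = motifs.pbs_logo(pbs_seqs)
            motifs.write_logo_matrix(profile, out / "pbs_logo.tsv")
        report.stage_counts["pbs_calls"] = len(pbs_rows)

    with open(out / "run_report.json", "w") as fh:
        json.dump(
            {
                "stage_counts": report.stage_counts,
                "parameters": report.parameters,
                "filters": report.filters,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return report


def _element_coordinate(
    alignment: structure.PairwiseAlignment, ref_pos: int
) -> Optional[int]:
    """1-based element coordinate of the element base aligned at or before
    a reference position."""
    pos = 0
    result = None
    for i in range(len(alignment.columns)):
        if alignment.aligned_element[i] != "-":
            pos += 1
            rp = int(alignment.ref_positions[i])
            if 0 < rp <= ref_pos:
                result = pos
    return result


# ---------------------------------------------------------------------------
# Catalog replay
# ---------------------------------------------------------------------------

def replay_catalog() -> dict[str, float]:
    """Recompute summary statistics from the packaged catalog tables.

    Ages are recomputed from the printed divergences with the clock
    relations (not read from the age columns); context percentages,
    length strata and screens are recounted from the raw rows.
    """
    tables = load_catalog()
    prov, solo = tables["proviruses"], tables["solo_ltrs"]
    integ, dat = tables["integrity"], tables["dating"]

    gt70, mid, lt40 = discovery.stratify_lengths(prov.coverage_pct)
    prov_summary = landscape.summarize_context(list(prov.context))
    solo_summary = landscape.summarize_context(list(solo.context))

    def pct_of(summary: pd.DataFrame, category: str) -> float:
        row = summary[summary.category == category]
        return float(row.percent.iloc[0]) if len(row) else 0.0

    solo_pass = int((solo.ltr_pct > 90.0).sum())

    ltr_ages = []
    internal_ages = []
    by_locus_ltr: dict[str, float] = {}
    by_locus_internal: dict[str, float] = {}
    for rec in dat.itertuples():
        ds = {
            r: (None if pd.isna(getattr(rec, f"d_{r}")) else float(getattr(rec, f"d_{r}")))
            for r in ("gag", "pro", "pol", "env")
        }
        _, age_int = dating.date_internal(ds)
        if age_int is not None:
            internal_ages.append(age_int)
            by_locus_internal[rec.locus] = age_int
        if not pd.isna(rec.d_ltr):
            age_ltr = dating.age_from_divergence(
                float(rec.d_ltr), paired_ltr=True
            )
            ltr_ages.append(age_ltr)
            by_locus_ltr[rec.locus] = age_ltr

    region_counts = {
        region: int((integ[region] > 90.0).sum())
        for region in ("gag", "pro", "pol", "env")
    }

    return {
        "provirus_count": float(len(prov)),
        "solo_ltr_count": float(len(solo)),
        "elements_gt70_pct_count": float(gt70),
        "elements_40_70_pct_count": float(mid),
        "elements_lt40_pct_count": float(lt40),
        "provirus_intergenic_pct": pct_of(prov_summary, "Intergenic"),
        "provirus_intron_pct": pct_of(prov_summary, "Intron"),
        "provirus_exon_intron_pct": pct_of(prov_summary, "Exon_intron"),
        "solo_intergenic_pct": pct_of(solo_summary, "Intergenic"),
        "solo_intron_pct": pct_of(solo_summary, "Intron"),
        "solo_screen_pass_count": float(solo_pass),
        "solo_screen_pass_pct": round(100.0 * solo_pass / len(solo), 2),
        "mean_ltr_age_my": round(float(np.mean(ltr_ages)), 2),
        "min_ltr_age_my": round(float(np.min(ltr_ages)), 2),
        "max_ltr_age_my": round(float(np.max(ltr_ages)), 2),
        "mean_internal_age_my": round(float(np.mean(internal_ages)), 2),
        "min_internal_age_my": round(float(np.min(internal_ages)), 2),
        "max_internal_age_my": round(float(np.max(internal_ages)), 2),
        "ltr_age_16p12_3_my": round(by_locus_ltr["16p12.3"], 5),
        "internal_age_8q24_3_my": round(by_locus_internal["8q24.3"], 2),
        "gag_screen_count": float(region_counts["gag"]),
        "pro_screen_count": float(region_counts["pro"]),
        "pol_screen_count": float(region_counts["pol"]),
        "env_screen_count": float(region_counts["env"]),
        "n_ltr_dated": float(len(ltr_ages)),
        "n_internal_dated": float(len(internal_ages)),
    }


# ---------------------------------------------------------------------------
# Demo inputs
# ---------------------------------------------------------------------------

def make_demo_inputs(
    directory: str | Path, seed: int = 0
) -> PipelineConfig:
    """Write a small synthetic input set and return a ready config.

    Two chromosomes of 400 kb, 20 genes, 3 planted proviruses (ages 10,
    20 and 30 my; one with a pol deletion) and 5 solo LTRs, plus a
    synthetic tRNA library and a toy category table.
    """
    from . import synthetic

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trna_lib = synthetic.make_trna_library(seed + 1)
    reference = synthetic.make_reference(seed + 2, trna_lib=trna_lib)
    plants = [
        synthetic.PlantSpec(
            "full_provirus", "chr1", "+", true_age_my=10.0,
            context_target="intergenic",
        ),
        synthetic.PlantSpec(
            "full_provirus", "chr2", "-", true_age_my=20.0,
            context_target="intergenic",
        ),
        synthetic.PlantSpec(
            "deleted_provirus", "chr1", "+", true_age_my=30.0,
            deletions=((4000, 5500),), context_target="intergenic",
        ),
        synthetic.PlantSpec(
            "solo_LTR", "chr1", "+", true_age_my=15.0,
            context_target="intron",
        ),
        synthetic.PlantSpec(
            "solo_LTR", "chr1", "-", true_age_my=25.0,
            context_target="intergenic",
        ),
        synthetic.PlantSpec(
            "solo_LTR", "chr2", "+", true_age_my=35.0,
            context_target="intergenic",
        ),
        synthetic.PlantSpec(
            "solo_LTR", "chr2", "-", true_age_my=20.0,
            context_target="intron",
        ),
        synthetic.PlantSpec(
            "solo_LTR", "chr2", "+", true_age_my=10.0,
            context_target="intergenic",
        ),
    ]
    config_obj = synthetic.GenomeConfig(
        chromosomes={"chr1": 400_000, "chr2": 400_000},
        n_genes=20,
        plants=tuple(plants),
    )
    synthetic.generate_genome(
        config_obj, seed, reference=reference, out_dir=directory
    )
    synthetic.write_trna_fasta(trna_lib, directory / "trna.fasta")
    # toy category table over the synthetic gene ids
    with open(directory / "categories.tsv", "w") as fh:
        fh.write("category_id\tgene_id\n")
        for i in range(1, 21):
            fh.write(f"CAT:{'even' if i % 2 == 0 else 'odd'}\tgene{i}\n")
            if i <= 10:
                fh.write(f"CAT:low\tgene{i}\n")
    return PipelineConfig(
        genome=str(directory / "genome.fasta"),
        reference=str(directory / "reference.fasta"),
        regions=str(directory / "reference.regions.tsv"),
        genes=str(directory / "genes.gff3"),
        trna_lib=str(directory / "trna.fasta"),
        categories=str(directory / "categories.tsv"),
        out_dir=str(directory / "out"),
        seed=seed,
    )
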
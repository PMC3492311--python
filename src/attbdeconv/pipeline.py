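"""Pipeline orchestration: simulate -> demux -> detect -> resolve ->
quantify -> annotate -> nominate, with a reproducible manifest.

The pipeline mirrors the screen's informatic read-out: reads are binned by
library barcode, attB junctions are detected per read and resolved through
the alignments, and each library is quantified and annotated separately
(expression ranking is only meaningful within one library's amplified
pool).  All stages are deterministic; rerunning the same configuration
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path

import pandas as pd
import pysam

from . import __version__
from .colorspace import read_color_file
from .junction import (
    aggregate_fusion_sites,
    demultiplex,
    detect_attb,
    load_fastq,
    resolve_fusion_coordinate,
    write_fusion_bed,
)
from .quantvar import (
    call_variants,
    compute_fpkm,
    count_fragments,
    detect_exon_skips,
    nominate_candidates,
    quant_table,
)
from .refmodel import Genome, load_gene_models
from .screen_sim import InsertSpec, SimConfig, synthetic_reference

__all__ = [
    "PipelineConfig",
    "run_deconvolution",
    "load_barcodes",
    "demo_reference",
    "demo_sim_config",
]


@dataclasses.dataclass
class PipelineConfig:
    """Paths and thresholds for one deconvolution run."""

    reads1: str
    genome_fasta: str
    gene_bed: str
    barcodes_tsv: str
    alignments_sam: str
    out_dir: str
    space: str = "base"
    max_mismatches: int = 0
    barcode_mismatches: int = 0
    min_flank: int = 5
    top_k: int = 10
    min_sites: int = 3
    min_skip_reads: int = 2
    min_depth: int = 10
    min_alt_frac: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for attr in ("reads1", "genome_fasta", "gene_bed", "barcodes_tsv",
                     "alignments_sam"):
            path = getattr(self, attr)
            if not Path(path).exists():
                raise FileNotFoundError(f"config.{attr}: no such file: {path}")
        if self.space not in ("base", "color"):
            raise ValueError("space must be 'base' or 'color'")
        if not (0 < self.min_alt_frac <= 1):
            raise ValueError("min_alt_frac must be in (0, 1]")
        if min(self.min_flank, self.top_k, self.min_sites,
               self.min_skip_reads, self.min_depth) < 1:
            raise ValueError("thresholds must be >= 1")

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_barcodes(path: str) -> dict[str, str]:
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                lib, bc = line.split()[:2]
                table[lib] = bc
    return table


def _strip(qname: str) -> str:
    return qname[:-2] if qname.endswith(("/1", "/2")) else qname


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write_df(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, float_format="%.10g")
    os.replace(tmp, path)


def run_deconvolution(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle.

    Outputs under ``config.out_dir``: per-library fusion-site BED files,
    gene quantification, variant, exon-skip and candidate TSVs (one row set
    per library), plus a manifest with input checksums and thresholds.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = Genome.from_fasta(config.genome_fasta)
    genes = load_gene_models(config.gene_bed)
    barcodes = load_barcodes(config.barcodes_tsv)

    if config.space == "color":
        reads1 = list(read_color_file(config.reads1))
    else:
        reads1 = load_fastq(config.reads1)

    with pysam.AlignmentFile(config.alignments_sam, "r") as sam:
        records = list(sam)
    by_qname: dict[str, list[pysam.AlignedSegment]] = {}
    for rec in records:
        by_qname.setdefault(_strip(rec.query_name), []).append(rec)

    assigned, unassigned = demultiplex(reads1, barcodes,
                                       config.barcode_mismatches)
    lib_of_qname = {
        _strip(r.read_id): lib for lib, rs in assigned.items() for r in rs
    }

    quant_frames, cand_frames, var_rows, skip_rows, summary_frames = (
        [], [], [], [], []
    )
    outputs: dict[str, Path] = {}
    for lib in sorted(assigned):
        lib_reads = assigned[lib]
        # junction detection + coordinate resolution
        per_read_sites = []
        for read in lib_reads:
            for hit in detect_attb(read, space=config.space,
                                   max_mismatches=config.max_mismatches,
                                   library_id=lib):
                for aln in by_qname.get(_strip(read.read_id), []):
                    if aln.is_read2 or aln.is_unmapped:
                        continue
                    site = resolve_fusion_coordinate(
                        hit, aln, genes, min_flank=config.min_flank
                    )
                    if site is not None:
                        per_read_sites.append(site)
        site_table, summary = aggregate_fusion_sites(per_read_sites)
        bed_path = out / f"fusion_sites.{lib}.bed"
        write_fusion_bed(str(bed_path), site_table)
        outputs[f"fusion_sites.{lib}.bed"] = bed_path
        summary = summary.assign(library_id=lib)
        summary_frames.append(summary)

        # quantification
        lib_records = [
            r for r in records if lib_of_qname.get(_strip(r.query_name)) == lib
        ]
        counts, total = count_fragments(lib_records, genes)
        quants = compute_fpkm(counts, genes, max(total, 1))
        qdf = quant_table(quants).assign(library_id=lib)
        quant_frames.append(qdf)

        # variants and exon skips
        variants = call_variants(lib_records, genome, genes,
                                 min_depth=config.min_depth,
                                 min_alt_frac=config.min_alt_frac)
        for v in variants:
            var_rows.append(
                {
                    "library_id": lib, "gene_id": v.gene_id, "tpos": v.tpos,
                    "ref": v.ref, "alt": v.alt, "depth": v.depth,
                    "alt_count": v.alt_count, "vaf": round(v.vaf, 2),
                    "consequence_kind": v.consequence.kind,
                    "consequence": str(v.consequence),
                }
            )
        skips = []
        for g in genes:
            for ev in detect_exon_skips(lib_records, g,
                                        min_reads=config.min_skip_reads):
                skips.append(ev)
                skip_rows.append(
                    {
                        "library_id": lib, "gene_id": ev.gene_id,
                        "exon_index": ev.exon_index,
                        "junction_reads": ev.junction_reads,
                    }
                )
        report = nominate_candidates(
            quants, summary, variants, skips,
            top_k=config.top_k, min_sites=config.min_sites,
        ).assign(library_id=lib)
        cand_frames.append(report)

    var_cols = ["library_id", "gene_id", "tpos", "ref", "alt", "depth",
                "alt_count", "vaf", "consequence_kind", "consequence"]
    skip_cols = ["library_id", "gene_id", "exon_index", "junction_reads"]
    tables = {
        "gene_quant.tsv": pd.concat(quant_frames, ignore_index=True),
        "fusion_summary.tsv": pd.concat(summary_frames, ignore_index=True),
        "variants.tsv": pd.DataFrame(var_rows, columns=var_cols),
        "exon_skips.tsv": pd.DataFrame(skip_rows, columns=skip_cols),
        "candidates.tsv": pd.concat(cand_frames, ignore_index=True),
    }
    for name, df in tables.items():
        path = out / name
        _atomic_write_df(df, path)
        outputs[name] = path

    manifest = {
        "tool": "attbdeconv",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_reads": len(reads1),
        "n_unassigned": len(unassigned),
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("reads1", "genome_fasta", "gene_bed",
                         "barcodes_tsv", "alignments_sam")
        },
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    manifest_path = out / "manifest.json"
    tmp = manifest_path.with_suffix(".json.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, manifest_path)
    outputs["manifest.json"] = manifest_path
    return outputs


def monoclonal_vaf_study(seed: int, out_dir: str | Path,
                         fragments: int = 8000):
    """Measure pileup VAF in a monoclonal transformant.

    Simulates one clone carrying a single insert species with one planted
    substitution at zero error rate, then runs the pileup at the variant's
    genomic site.  Returns (pileup result, genomic site, transcript
    position).  With every integrated copy mutant, the expected VAF is
    100%.
    """
    import pysam

    from .quantvar import pileup_vaf
    from .refmodel import transcript_to_genome
    from .screen_sim import simulate_screen

    genome, genes = synthetic_reference(n_genes=4, seed=seed)
    gene = next(g for g in genes if g.cds_start_tpos >= 50)
    var_tpos, var_alt = _pick_missense(genome, gene)
    config = SimConfig(
        n_libraries=1, clones_per_library=1, inserts_per_clone_mean=1,
        insert_pool=(InsertSpec(gene.gene_id, variants=((var_tpos, var_alt),),
                                trunc_choices=(1,)),),
        fragments_per_library=fragments, seed=seed,
    )
    bundle = simulate_screen(config, genome, genes, out_dir)
    chrom, gpos, _ = transcript_to_genome(gene, var_tpos)
    with pysam.AlignmentFile(str(bundle.truth_sam)) as fh:
        result = pileup_vaf(fh, genome, (chrom, gpos))
    return result, (chrom, gpos), var_tpos


# ---------------------------------------------------------------------------
# demo / acceptance study conditions


def demo_reference(seed: int = 0):
    """Reference used by the bundled demo screen (24 random genes)."""
    return synthetic_reference(n_genes=24, seed=seed)


def _pick_missense(genome: Genome, gene) -> tuple[int, str]:
    """First CDS position/alt allele giving a missense change."""
    from .quantvar import annotate_substitution
    from .refmodel import transcript_seq

    tseq = transcript_seq(genome, gene)
    for tpos in range(gene.cds_start_tpos, min(len(tseq), gene.cds_start_tpos + 300)):
        ref = tseq[tpos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            cons = annotate_substitution(gene, tpos, ref, alt, tseq)
            if cons.kind == "missense":
                return tpos, alt
    raise RuntimeError(f"no missense position found in {gene.gene_id}")


def demo_sim_config(
    seed: int = 0,
    n_libraries: int = 3,
    fragments_per_library: int = 12000,
    k_truncations: int = 4,
    space: str = "base",
) -> tuple[SimConfig, Genome, list]:
    """Scaled-down screen: 3 libraries, 10 clones each, Poisson-7 inserts.

    One driver gene is planted into every clone of the first library with
    ``k_truncations`` distinct 5' truncation points and a missense
    substitution; a second gene contributes an exon-16-style internal-exon
    skip; the remaining genes act as unmutated housekeeping background.
    """
    genome, genes = demo_reference(seed)
    driver = next(
        g for g in genes
        if g.cds_start_tpos >= 150 and len(g.exons) >= 3
    )
    trunc_step = max(1, (driver.cds_start_tpos - 20) // k_truncations)
    trunc_choices = tuple(1 + i * trunc_step for i in range(k_truncations))
    var_tpos, var_alt = _pick_missense(genome, driver)
    skip_gene = next(
        g for g in genes
        if g.gene_id != driver.gene_id and len(g.exons) >= 4
    )
    pool = tuple(
        InsertSpec(g.gene_id)
        for g in genes
        if g.gene_id not in (driver.gene_id, skip_gene.gene_id)
    ) + (InsertSpec(skip_gene.gene_id, skipped_exons=(2,), weight=1.0),)
    config = SimConfig(
        n_libraries=n_libraries,
        clones_per_library=10,
        inserts_per_clone_mean=7.0,
        insert_pool=pool,
        fragments_per_library=fragments_per_library,
        space=space,
        seed=seed,
        driver=InsertSpec(
            driver.gene_id,
            variants=((var_tpos, var_alt),),
            trunc_choices=trunc_choices,
        ),
        driver_libraries=("lib01",),
    )
    return config, genome, genes
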
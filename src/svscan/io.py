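"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA/SAM reading goes through pyfaidx/pysam; VCF writing through pysam.
PAF is a 12+ column TSV with a cg:Z CIGAR tag (no parser exists in the
scientific stack, so the few lines it takes live here).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .models import (
    AlignmentBlock,
    Call,
    GeneModel,
    StructuralVariant,
    SvType,
    cigar_spans,
    parse_cigar,
)

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def seq_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def str_to_seq(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()


def write_fasta(genome: Mapping[str, np.ndarray], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, arr in genome.items():
            fh.write(f">{name}\n")
            seq = seq_to_str(arr)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    """Whole-genome load as name -> ASCII uint8 array (pyfaidx-backed)."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str_to_seq(str(fa[name][:])) for name in fa.keys()}


# ---------------------------------------------------------------- PAF

class PafParseError(ValueError):
    pass


def write_paf(blocks: Iterable[AlignmentBlock], path: str | Path,
              query_lens: Mapping[str, int], ref_lens: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            ops = parse_cigar(b.cigar)
            ref_span, q_span = cigar_spans(ops)
            matches = sum(n for n, op in ops if op in "M=")
            alnlen = sum(n for n, op in ops if op in "M=XID")
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.query_name, query_lens[b.query_name], b.query_start, b.query_end,
                        b.strand,
                        b.ref_name, ref_lens[b.ref_name], b.ref_start, b.ref_end,
                        matches, alnlen, b.mapq, f"cg:Z:{b.cigar}",
                    )
                )
                + "\n"
            )


def parse_paf(path: str | Path) -> tuple[list[AlignmentBlock], dict]:
    """Parse PAF into validated AlignmentBlocks.

    Blocks whose CIGAR-consumed lengths disagree with the stated coordinate
    spans are rejected (counted in the report); a missing cg:Z tag raises.
    """
    blocks: list[AlignmentBlock] = []
    report = {"n_lines": 0, "n_accepted": 0, "n_rejected": 0, "rejected_lines": []}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            report["n_lines"] += 1
            cols = line.split("\t")
            if len(cols) < 12:
                raise PafParseError(f"line {lineno}: expected >=12 columns, got {len(cols)}")
            cigar = None
            for tag in cols[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = tag[5:]
                    break
            if cigar is None:
                raise PafParseError(f"line {lineno}: missing cg:Z CIGAR tag")
            block = AlignmentBlock(
                ref_name=cols[5], ref_start=int(cols[7]), ref_end=int(cols[8]),
                query_name=cols[0], query_start=int(cols[2]), query_end=int(cols[3]),
                strand=cols[4], cigar=cigar, mapq=int(cols[11]),
            )
            ref_span, q_span = cigar_spans(parse_cigar(cigar))
            if (ref_span != block.ref_end - block.ref_start
                    or q_span != block.query_end - block.query_start
                    or block.ref_start >= block.ref_end
                    or block.query_start >= block.query_end):
                report["n_rejected"] += 1
                report["rejected_lines"].append(lineno)
                continue
            report["n_accepted"] += 1
            blocks.append(block)
    return blocks, report


# ---------------------------------------------------------------- VCF

def _sv_vcf_header(contigs: Mapping[str, int], samples: Iterable[str] = ()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant (INS or DEL)")
    header.info.add("SVLEN", 1, "Integer", "SV length (bp); negative for deletions")
    header.info.add("BCHROM", 1, "String", "Chromosome in the second (B) assembly")
    header.info.add("BSTART", 1, "Integer", "1-based start in the second (B) assembly")
    header.info.add("BEND", 1, "Integer", "1-based end in the second (B) assembly")
    header.info.add("ORIGIN", 1, "String", "Caller path: within_alignment or between_alignment")
    if samples:
        header.formats.add("GT", 1, "String", "Genotype (B-allele dosage encoding)")
        header.formats.add("AD", "R", "Integer",
                           "Clean spanning read support (A allele, B allele)")
        for s in samples:
            header.add_sample(s)
    return header


def write_sv_vcf(svs: Iterable[StructuralVariant], contigs: Mapping[str, int],
                 path: str | Path, genotypes: pd.DataFrame | None = None,
                 supports: Mapping[tuple[str, str], tuple[int, int]] | None = None) -> None:
    """Write SVs as symbolic VCF v4.2 records (1-based POS).

    ``genotypes``: loci x accessions B-allele dosage (NaN missing).
    """
    samples = list(genotypes.columns) if genotypes is not None else []
    header = _sv_vcf_header(contigs, samples)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    # htslib warns transiently while END is re-encoded for zero-width
    # insertion breakpoints even though the written record is correct
    verbosity = pysam.set_verbosity(0)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for sv in svs:
            rec = vf.new_record()
            rec.contig = sv.ref_name
            rec.start = sv.ref_start  # POS = SV start; symbolic alleles carry no pad base
            rec.alleles = ("N", "<INS>" if sv.type == SvType.INSERTION else "<DEL>")
            rec.stop = max(sv.ref_end, sv.ref_start + 1)  # writes INFO/END
            rec.id = sv.id
            rec.info["SVTYPE"] = "INS" if sv.type == SvType.INSERTION else "DEL"
            rec.info["SVLEN"] = sv.size if sv.type == SvType.INSERTION else -sv.size
            rec.info["ORIGIN"] = sv.origin
            if sv.query_name is not None:
                rec.info["BCHROM"] = sv.query_name
                rec.info["BSTART"] = sv.query_start + 1
                rec.info["BEND"] = max(sv.query_end, sv.query_start + 1)
            if genotypes is not None:
                row = genotypes.loc[sv.id]
                for acc in samples:
                    d = row[acc]
                    rec.samples[acc]["GT"] = (None, None) if pd.isna(d) else gt_map[int(d)]
                    if supports is not None and (sv.id, acc) in supports:
                        rec.samples[acc]["AD"] = supports[(sv.id, acc)]
            vf.write(rec)
    pysam.set_verbosity(verbosity)


def read_sv_vcf(path: str | Path) -> tuple[list[StructuralVariant], pd.DataFrame | None]:
    """Read symbolic SV VCF back to StructuralVariants (+ dosage matrix if genotyped)."""
    svs: list[StructuralVariant] = []
    rows = {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            svtype = SvType.INSERTION if rec.info["SVTYPE"] == "INS" else SvType.DELETION
            size = abs(rec.info["SVLEN"])
            ref_start = rec.start
            ref_end = ref_start if svtype == SvType.INSERTION else ref_start + size
            q_name = rec.info.get("BCHROM")
            q_start = rec.info["BSTART"] - 1 if "BSTART" in rec.info else None
            q_end = None
            if "BEND" in rec.info:
                q_end = q_start if svtype == SvType.DELETION else rec.info["BEND"]
            svs.append(StructuralVariant(
                id=rec.id, ref_name=rec.contig, ref_start=ref_start, ref_end=ref_end,
                size=size, type=svtype, origin=rec.info.get("ORIGIN", "within_alignment"),
                query_name=q_name, query_start=q_start, query_end=q_end,
            ))
            if samples:
                row = {}
                for acc in samples:
                    gt = rec.samples[acc].get("GT")
                    row[acc] = np.nan if gt is None or gt[0] is None else float(sum(gt))
                rows[rec.id] = row
    geno = pd.DataFrame.from_dict(rows, orient="index") if rows else None
    if geno is not None and len(svs):
        geno = geno.loc[[sv.id for sv in svs]]
    return svs, geno


def write_snp_vcf(sites: pd.DataFrame, dosages: pd.DataFrame | None,
                  contigs: Mapping[str, int], path: str | Path) -> None:
    """Write biallelic SNPs; ``sites`` columns: chrom, pos (0-based), ref, alt."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    samples = list(dosages.columns) if dosages is not None else []
    if samples:
        header.formats.add("GT", 1, "String", "Genotype")
        for s in samples:
            header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, (_, site) in enumerate(sites.iterrows()):
            rec = vf.new_record()
            rec.contig = site["chrom"]
            rec.start = int(site["pos"])
            rec.alleles = (site["ref"], site["alt"])
            rec.id = site.get("id", f"snp{i}")
            if samples:
                row = dosages.iloc[i]
                for acc in samples:
                    d = row[acc]
                    rec.samples[acc]["GT"] = (None, None) if pd.isna(d) else gt_map[int(d)]
            vf.write(rec)


def read_snp_panel(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a biallelic SNP VCF → (sites df, accessions x sites dosage df)."""
    sites = []
    dosage_rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if len(rec.alleles) != 2:
                continue
            sites.append({"chrom": rec.contig, "pos": rec.start,
                          "ref": rec.alleles[0], "alt": rec.alleles[1],
                          "id": rec.id or f"{rec.contig}:{rec.pos}"})
            row = []
            for acc in samples:
                gt = rec.samples[acc].get("GT")
                row.append(np.nan if gt is None or gt[0] is None else float(sum(gt)))
            dosage_rows.append(row)
    sites_df = pd.DataFrame(sites)
    dos = pd.DataFrame(np.array(dosage_rows).T if dosage_rows else np.empty((len(samples), 0)),
                       index=samples, columns=list(sites_df.get("id", [])))
    return sites_df, dos


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join(map(str, (
                g.chrom, "svscan_sim", "gene", g.start + 1, g.end, ".", g.strand, ".",
                f"ID={g.gene_id}"))) + "\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write("\t".join(map(str, (
                g.chrom, "svscan_sim", "mRNA", g.start + 1, g.end, ".", g.strand, ".",
                f"ID={mrna_id};Parent={g.gene_id}"))) + "\n")
            for i, (es, ee) in enumerate(sorted(g.exons), start=1):
                fh.write("\t".join(map(str, (
                    g.chrom, "svscan_sim", "exon", es + 1, ee, ".", g.strand, ".",
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}"))) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load GFF3 gene models (gene/mRNA/exon) into 0-based half-open GeneModels."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = set()
        for child in db.children(g, featuretype="exon"):
            exons.add((child.start - 1, child.end))
        genes.append(GeneModel(gene_id=g.id, chrom=g.seqid, start=g.start - 1,
                               end=g.end, strand=g.strand, exons=sorted(exons)))
    return genes


# ---------------------------------------------------------------- tables

def write_groups_tsv(groups: pd.Series, path: str | Path) -> None:
    groups.rename("group").rename_axis("accession").to_frame().to_csv(path, sep="\t")


def read_groups_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)


def write_sv_truth_tsv(svs: Iterable[StructuralVariant], path: str | Path) -> None:
    rows = [{
        "sv_id": sv.id, "chrom": sv.ref_name, "ref_start": sv.ref_start,
        "ref_end": sv.ref_end, "size": sv.size, "type": sv.type.value,
        "b_chrom": sv.query_name, "b_start": sv.query_start, "b_end": sv.query_end,
    } for sv in svs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


CALL_ORDER = [Call.REF_A, Call.HET, Call.REF_B, Call.MISSING]
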
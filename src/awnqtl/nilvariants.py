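"""NIL transcript-variant analysis: hard filtering, allele-origin calls,
introgression intervals, candidate shortlisting and indel effects.

Variant records carry the annotations the hard filter consumes (QUAL, FS,
QD, DP) plus a genotype call against the recipient reference.  The filter
keeps records with QUAL >= 30, Fisher-strand FS <= 30.0, quality-by-depth
QD >= 2.0 and read depth strictly greater than 4.  A gene is assigned wild
origin when it carries at least one passing homozygous-alternate SNP
(the reference being the recipient); genes with only heterozygous variants
stay recipient-origin and are flagged as segregating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import logger

__all__ = [
    "VariantRecord",
    "GeneOriginCall",
    "SegregatingInterval",
    "filter_variants",
    "classify_gene_origin",
    "detect_segregating_intervals",
    "candidate_shortlist",
    "indel_effect",
    "read_vcf",
]

QUAL_MIN = 30.0
FS_MAX = 30.0
QD_MIN = 2.0
DP_MIN_EXCLUSIVE = 4  # "coverage exceeded four reads": DP > 4


@dataclass(frozen=True)
class VariantRecord:
    gene: str
    chromosome: str | None
    position_cm: float | None
    qual: float
    fs: float | None
    qd: float | None
    dp: int
    genotype: str  # hom_ref | het | hom_alt
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.dp < 0:
            raise ValueError(f"negative read depth on {self.gene}")
        if self.qual < 0:
            raise ValueError(f"negative QUAL on {self.gene}")
        if self.genotype not in ("hom_ref", "het", "hom_alt"):
            raise ValueError(f"unknown genotype call {self.genotype!r}")


def filter_variants(records: list[VariantRecord]) -> list[VariantRecord]:
    """Hard filter: QUAL >= 30, FS <= 30.0, QD >= 2.0, DP > 4.

    Order-preserving and idempotent; a missing FS or QD annotation passes
    that single criterion (logged).  Records with negative depth raise at
    construction, so every input record here is well formed."""
    out = []
    for rec in records:
        if rec.fs is None or rec.qd is None:
            logger.info("variant on %s missing FS/QD annotation; criterion passed", rec.gene)
        if rec.qual < QUAL_MIN:
            continue
        if rec.fs is not None and rec.fs > FS_MAX:
            continue
        if rec.qd is not None and rec.qd < QD_MIN:
            continue
        if rec.dp <= DP_MIN_EXCLUSIVE:
            continue
        out.append(rec)
    return out


@dataclass(frozen=True)
class GeneOriginCall:
    gene: str
    chromosome: str | None
    position_cm: float | None
    origin: str  # recipient | wild
    supporting_variants: int
    het_only: bool = False

    def __post_init__(self) -> None:
        if self.origin == "wild" and self.supporting_variants < 1:
            raise ValueError("wild origin requires supporting variants")


def classify_gene_origin(passing: list[VariantRecord]) -> list[GeneOriginCall]:
    """Per-gene allele origin from passing records.

    Wild origin needs >= 1 homozygous-alternate SNP; genes whose passing
    records are all heterozygous are called recipient with a het-only flag."""
    by_gene: dict[str, list[VariantRecord]] = {}
    for rec in passing:
        by_gene.setdefault(rec.gene, []).append(rec)
    calls = []
    for gene, recs in by_gene.items():
        hom_alt = [r for r in recs if r.genotype == "hom_alt"]
        het = [r for r in recs if r.genotype == "het"]
        chrom = recs[0].chromosome
        pos = recs[0].position_cm
        if hom_alt:
            calls.append(GeneOriginCall(gene, chrom, pos, "wild", len(hom_alt)))
        else:
            calls.append(
                GeneOriginCall(gene, chrom, pos, "recipient", 0, het_only=bool(het))
            )
    return calls


@dataclass(frozen=True)
class SegregatingInterval:
    chromosome: str
    start_cm: float
    end_cm: float
    genes: list[str]
    hc_count: int = 0
    lc_count: int = 0

    @property
    def width_cm(self) -> float:
        return self.end_cm - self.start_cm


def detect_segregating_intervals(
    calls_a: list[GeneOriginCall],
    calls_b: list[GeneOriginCall],
    gap_tolerance: float = 1.0,
    confidence_class: dict[str, str] | None = None,
) -> list[SegregatingInterval]:
    """Intervals where two NILs carry different allele origins.

    Genes present in both call sets whose origins differ are polymorphic;
    maximal runs of consecutive polymorphic genes along each chromosome
    (gaps smaller than ``gap_tolerance`` cM allowed) become intervals whose
    bounds are the outermost polymorphic gene positions."""
    origin_b = {c.gene: c for c in calls_b}
    poly = []
    for c in calls_a:
        other = origin_b.get(c.gene)
        if other is None or c.chromosome is None or c.position_cm is None:
            continue
        if c.origin != other.origin:
            poly.append(c)
    intervals: list[SegregatingInterval] = []
    by_chrom: dict[str, list[GeneOriginCall]] = {}
    for c in poly:
        by_chrom.setdefault(c.chromosome, []).append(c)
    for chrom, genes in sorted(by_chrom.items()):
        genes.sort(key=lambda c: c.position_cm)
        run: list[GeneOriginCall] = []
        for c in genes:
            if run and c.position_cm - run[-1].position_cm >= gap_tolerance:
                intervals.append(_make_interval(chrom, run, confidence_class))
                run = []
            run.append(c)
        if run:
            intervals.append(_make_interval(chrom, run, confidence_class))
    return intervals


def _make_interval(chrom, run, confidence_class) -> SegregatingInterval:
    names = [c.gene for c in run]
    hc = lc = 0
    if confidence_class:
        hc = sum(1 for g in names if confidence_class.get(g) == "HC")
        lc = sum(1 for g in names if confidence_class.get(g) == "LC")
    return SegregatingInterval(chrom, run[0].position_cm, run[-1].position_cm, names, hc, lc)


# ---------------------------------------------------------------------------
# Candidate shortlist


def candidate_shortlist(
    interval_genes: list[str],
    detected: set[str],
    polymorphic: set[str],
    differentially_expressed: set[str],
) -> pd.DataFrame:
    """Filter-funnel candidate list for an interval.

    Candidates are interval genes with a detected transcript AND evidence
    (polymorphic or differentially expressed), ranked polymorphic+DE >
    polymorphic > DE.  The returned frame carries stage counts as attrs:
    total -> detected -> polymorphic."""
    rows = []
    for gene in interval_genes:
        det = gene in detected
        pol = gene in polymorphic
        de = gene in differentially_expressed
        if det and (pol or de):
            rank = 0 if (pol and de) else (1 if pol else 2)
            rows.append((gene, pol, de, rank))
    df = pd.DataFrame(rows, columns=["gene", "polymorphic", "differentially_expressed", "rank"])
    df = df.sort_values(["rank", "gene"], kind="stable").reset_index(drop=True)
    df.attrs["n_interval"] = len(interval_genes)
    df.attrs["n_detected"] = sum(1 for g in interval_genes if g in detected)
    df.attrs["n_polymorphic"] = sum(
        1 for g in interval_genes if g in detected and g in polymorphic
    )
    return df


# ---------------------------------------------------------------------------
# Indel effect on a CDS


@dataclass(frozen=True)
class IndelEffect:
    frame: str  # in_frame | frameshift
    premature_stop_codon: int | None  # 1-based codon index, None if absent


def indel_effect(cds: str, position: int, inserted: str) -> IndelEffect:
    """Consequence of inserting ``inserted`` after 1-based ``position``.

    The CDS must be a complete reading frame (length divisible by 3,
    starting with ATG).  A frameshift occurs when the insertion length is
    not a multiple of 3.  The mutated sequence is translated from the
    start; a stop codon appearing before the original terminal codon is
    reported as premature (1-based codon index)."""
    cds = cds.upper()
    inserted = inserted.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    if not 1 <= position <= len(cds):
        raise ValueError(f"position {position} outside CDS of length {len(cds)}")
    mutated = cds[:position] + inserted + cds[position:]
    frame = "in_frame" if len(inserted) % 3 == 0 else "frameshift"
    original_stop = len(cds) // 3  # the terminal codon of the intact CDS
    usable = mutated[: 3 * (len(mutated) // 3)]
    protein = str(Seq(usable).translate())
    stop_at = protein.find("*")
    premature = None
    if stop_at != -1 and stop_at + 1 < original_stop:
        premature = stop_at + 1
    return IndelEffect(frame, premature)


# ---------------------------------------------------------------------------
# VCF input (v4.2 subset)


def read_vcf(path, gene_positions: pd.DataFrame | None = None) -> list[VariantRecord]:
    """Read a VCF subset into VariantRecords.

    The gene id is taken from the CHROM field (transcript-aligned calls);
    ``gene_positions`` (columns gene, chromosome, position) optionally maps
    genes onto the genetic map.  Uses the first sample's GT."""
    import pysam

    pos_of = {}
    if gene_positions is not None:
        for _, row in gene_positions.iterrows():
            pos_of[str(row["gene"])] = (str(row["chromosome"]), float(row["position"]))
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            gene = rec.chrom
            chrom, cm = pos_of.get(gene, (None, None))
            info = rec.info
            fs = float(info["FS"]) if "FS" in info else None
            qd = float(info["QD"]) if "QD" in info else None
            dp = int(info["DP"]) if "DP" in info else 0
            if samples:
                gt = rec.samples[samples[0]].get("GT", (None, None))
                alleles = [a for a in gt if a is not None]
                if not alleles:
                    genotype = "hom_ref"
                elif all(a == 0 for a in alleles):
                    genotype = "hom_ref"
                elif all(a > 0 for a in alleles) and len(set(alleles)) == 1:
                    genotype = "hom_alt"
                else:
                    genotype = "het"
            else:
                genotype = "hom_ref"
            records.append(
                VariantRecord(
                    gene=gene,
                    chromosome=chrom,
                    position_cm=cm,
                    qual=float(rec.qual if rec.qual is not None else 0.0),
                    fs=fs,
                    qd=qd,
                    dp=dp,
                    genotype=genotype,
                    ref=rec.ref or "",
                    alt=rec.alts[0] if rec.alts else "",
                )
            )
    return records
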
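"""Readers and writers for the standard interchange formats.

* VCF 4.x (via :mod:`cyvcf2`) with the functional annotation carried in an
  INFO subfield; the common ``ANN=`` pipe-delimited layout is the default
  dialect and a simple ``IMPACT=``/``GENE=`` key dialect is supported.
* PLINK-style 6-column whitespace-delimited pedigree files.
* TSV cohort genotype-count tables.
* BED for exported ROH segments (0-based half-open on disk, converted from
  the package's 1-based inclusive internal coordinates).
* YAML run configuration.

Only autosomal records are loaded; sex chromosomes and unplaced contigs
are dropped with a logged count.  Multi-allelic records are split into
one biallelic site per alternate allele, genotypes recoded as the count
of that allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (HET, HOM_ALT, HOM_REF, MISSING, CohortCounts,
                        GenotypeMatrix, Pedigree, PedigreeRecord, ROHSegment,
                        TriomapError, VariantSite)

log = logging.getLogger(__name__)

DEFAULT_AUTOSOMES = tuple(str(c) for c in range(1, 30))


@dataclass(frozen=True)
class AnnotationSpec:
    """Where to find gene and impact annotations in a VCF record.

    dialect ``"ann"``: a pipe-delimited INFO subfield (snpEff-style
    ``ANN=allele|annotation|impact|gene|...``); ``impact_index`` and
    ``gene_index`` are 0-based positions within the first entry.
    dialect ``"info_keys"``: plain INFO keys holding the values directly.
    """

    dialect: str = "ann"
    field: str = "ANN"
    impact_index: int = 2
    gene_index: int = 3
    impact_key: str = "IMPACT"
    gene_key: str = "GENE"


def read_vcf(path: str | Path, ann_spec: AnnotationSpec = AnnotationSpec(),
             autosomes: Sequence[str] = DEFAULT_AUTOSOMES) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Phasing is ignored (``0|1`` == ``0/1``); ``./.`` maps to the missing
    code.  Records whose annotation field is absent are retained with
    impact ``MODIFIER`` and counted in a single warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    autoset = set(autosomes)
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    n_skipped_chrom = 0
    n_missing_ann = 0

    for rec in vcf:
        chrom = rec.CHROM[3:] if rec.CHROM.startswith("chr") else rec.CHROM
        if chrom not in autoset:
            n_skipped_chrom += 1
            continue
        alts = rec.ALT
        if not alts:
            continue
        gene, impact, found = _parse_annotation(rec, ann_spec)
        if not found:
            n_missing_ann += 1
        if len(alts) == 1:
            calls = _calls_from_gt_types(rec, path)
            _append_site(sites, columns, chrom, rec.POS, rec.REF, alts[0],
                         gene, impact, calls)
        else:
            # split multi-allelic record: one biallelic site per alt allele
            genos = rec.genotypes
            for k, alt in enumerate(alts, start=1):
                calls = np.empty(len(samples), dtype=np.int8)
                for i, g in enumerate(genos):
                    a = [x for x in g[:-1]]
                    if len(a) < 2 or a[0] < 0 or a[1] < 0:
                        calls[i] = MISSING
                    else:
                        calls[i] = int(a[0] == k) + int(a[1] == k)
                _append_site(sites, columns, chrom, rec.POS, rec.REF, alt,
                             gene, impact, calls)
    if n_skipped_chrom:
        log.info("read_vcf: skipped %d non-autosomal records", n_skipped_chrom)
    if n_missing_ann:
        log.warning("read_vcf: %d records lacked the %s annotation field; "
                    "impact set to MODIFIER", n_missing_ann, ann_spec.field)

    if not sites:
        return GenotypeMatrix(samples, [], np.zeros((len(samples), 0), dtype=np.int8))
    order = sorted(range(len(sites)),
                   key=lambda i: (_ck(sites[i].chrom), sites[i].pos,
                                  sites[i].ref, sites[i].alt))
    sites = [sites[i] for i in order]
    calls = np.stack([columns[i] for i in order], axis=1)
    return GenotypeMatrix(samples, sites, calls)


def _ck(chrom: str) -> int:
    return int(chrom)


def _append_site(sites, columns, chrom, pos, ref, alt, gene, impact, calls):
    sites.append(VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt,
                             gene=gene, impact=impact))
    columns.append(calls)


def _parse_annotation(rec, spec: AnnotationSpec) -> tuple[str, str, bool]:
    if spec.dialect == "ann":
        raw = rec.INFO.get(spec.field)
        if raw is None:
            return "", "MODIFIER", False
        first = str(raw).split(",")[0].split("|")
        impact = first[spec.impact_index] if len(first) > spec.impact_index else "MODIFIER"
        gene = first[spec.gene_index] if len(first) > spec.gene_index else ""
        if impact not in ("HIGH", "MODERATE", "LOW", "MODIFIER"):
            impact = "MODIFIER"
        return gene, impact, True
    if spec.dialect == "info_keys":
        impact = rec.INFO.get(spec.impact_key)
        gene = rec.INFO.get(spec.gene_key)
        found = impact is not None
        impact = impact if impact in ("HIGH", "MODERATE", "LOW", "MODIFIER") else "MODIFIER"
        return (gene or ""), impact, found
    raise TriomapError(f"unknown annotation dialect {spec.dialect!r}")


def _calls_from_gt_types(rec, path) -> np.ndarray:
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    gt = np.asarray(rec.gt_types)
    out = np.full(gt.shape, MISSING, dtype=np.int8)
    out[gt == 0] = HOM_REF
    out[gt == 1] = HET
    out[gt == 3] = HOM_ALT
    return out


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              contig_lengths: Optional[dict[str, int]] = None) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file.

    The annotation is emitted in a minimal 4-field ``ANN=`` INFO subfield
    (``allele|annotation|impact|gene``) so that ``read_vcf`` with the
    default :class:`AnnotationSpec` round-trips losslessly.
    """
    path = Path(path)
    chroms = list(dict.fromkeys(s.chrom for s in matrix.sites))
    if contig_lengths is None:
        contig_lengths = {}
        for s in matrix.sites:
            contig_lengths[s.chrom] = max(contig_lengths.get(s.chrom, 0), s.pos)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=triomap\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={contig_lengths.get(c, 0)}>\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
                 'annotations: Allele|Annotation|Annotation_Impact|Gene_Name">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for j, site in enumerate(matrix.sites):
            ann = f"ANN={site.alt}|variant|{site.impact}|{site.gene}"
            gts = "\t".join(_GT_STRING[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\t"
                     f"PASS\t{ann}\tGT\t{gts}\n")


# -- pedigree ------------------------------------------------------------


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PLINK-style 6-column pedigree file.

    Columns: family, individual, sire, dam, sex (1/2/0), phenotype
    (2 = affected/case, anything else = unaffected).  Roles are derived:
    affected individuals are cases; the recorded parents of a case are
    sire/dam; everyone else is a control.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6:
            raise TriomapError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        rows.append(parts)
    case_parents: dict[str, str] = {}
    affected = {iid for _, iid, _, _, _, pheno in rows if pheno == "2"}
    for _, iid, sire, dam, _, pheno in rows:
        if pheno == "2":
            if sire != "0":
                case_parents[sire] = "sire"
            if dam != "0":
                case_parents[dam] = "dam"
    records = []
    for _, iid, sire, dam, sex, pheno in rows:
        if iid in affected:
            role = "case"
        else:
            role = case_parents.get(iid, "control")
        records.append(PedigreeRecord(iid=iid, sire=sire, dam=dam,
                                      sex=int(sex), role=role))
    return Pedigree(records)


def write_pedigree(pedigree: Pedigree, path: str | Path, family: str = "FAM1") -> None:
    with Path(path).open("w") as fh:
        for r in pedigree:
            pheno = 2 if r.role == "case" else 1
            fh.write(f"{family}\t{r.iid}\t{r.sire}\t{r.dam}\t{r.sex}\t{pheno}\n")


# -- cohort counts -------------------------------------------------------


def read_cohort_counts(path: str | Path) -> CohortCounts:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"variant_id": str, "population": str})
    return CohortCounts(df)


def write_cohort_counts(counts: CohortCounts, path: str | Path) -> None:
    df = counts.df.copy()
    df["includes_case"] = df["includes_case"].astype(int)
    df.to_csv(path, sep="\t", index=False)


# -- BED / coordinate conversion ----------------------------------------


def to_bed_interval(start_bp: int, end_bp: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open. Exact bijection."""
    return start_bp - 1, end_bp


def from_bed_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    return bed_start + 1, bed_end


def write_roh_bed(segments: Iterable[ROHSegment], path: str | Path) -> None:
    """Export ROH segments as BED: chrom, start, end, sample, n_snv."""
    with Path(path).open("w") as fh:
        for seg in segments:
            b0, b1 = to_bed_interval(seg.start_bp, seg.end_bp)
            fh.write(f"{seg.chrom}\t{b0}\t{b1}\t{seg.sample}\t{seg.n_snv}\n")


def read_roh_bed(path: str | Path) -> list[ROHSegment]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, b0, b1, sample, n_snv = line.split("\t")
        start, end = from_bed_interval(int(b0), int(b1))
        out.append(ROHSegment(sample=sample, chrom=chrom, start_bp=start,
                              end_bp=end, n_snv=int(n_snv)))
    return out


# -- YAML config ---------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
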
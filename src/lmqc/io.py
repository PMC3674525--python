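"""Readers and writers for PLINK text PED/MAP and VCF genotype data.

Everything is recoded internally to minor-allele dosage, the minor
allele being determined dataset-wide (after excluding individuals with
missing phenotype) with ties at frequency 0.5 broken by lexicographic
allele order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import MISSING, GenotypeMatrix, PhenotypeVector


class ParseError(ValueError):
    pass


@dataclass
class DatasetBundle:
    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector
    sample_ids: np.ndarray
    source: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _dosage_from_alleles(pairs: np.ndarray, snp_label: str, log: list):
    """Minor-allele dosage codes plus (minor, major) for one SNP.

    ``pairs`` is an N x 2 array of allele strings, '0' meaning no call.
    Returns None when the SNP is not biallelic.
    """
    flat = pairs.ravel()
    called = flat != "0"
    alleles, counts = np.unique(flat[called], return_counts=True)
    if alleles.size > 2:
        log.append(("snp_dropped_multiallelic", snp_label))
        return None
    if alleles.size == 0:
        minor, major = "0", "0"
    elif alleles.size == 1:
        minor, major = alleles[0], alleles[0]  # monomorphic: dosage all 0
    else:
        order = np.argsort(counts, kind="stable")
        if counts[0] == counts[1]:
            minor, major = sorted(alleles)
        else:
            minor, major = alleles[order[0]], alleles[order[1]]
    codes = np.full(pairs.shape[0], MISSING, dtype=np.int8)
    row_called = (pairs != "0").all(axis=1)
    codes[row_called] = (pairs[row_called] == minor).sum(axis=1)
    if alleles.size == 1:
        codes[row_called] = 0
    return codes, (minor, major)


def _sort_snps(chrom, pos, order_within=None):
    """Stable sort indices by (chromosome, position)."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    return np.lexsort((pos, chrom))


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path) -> DatasetBundle:
    """Load a PLINK text fileset.

    PED column 6 phenotype: 2 -> case (1), 1 -> control (0), 0/-9 ->
    missing (individual excluded, logged).  Genotype '0 0' -> missing.
    """
    log: list = []
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 4:
            raise ParseError(f"{map_path}:{ln}: expected 4 MAP fields, got {len(f)}")
        map_rows.append((f[0], f[1], int(f[3])))
    m = len(map_rows)

    sample_ids, phenos, allele_rows = [], [], []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * m:
            raise ParseError(
                f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(f)}")
        sample_ids.append(f[1])
        phenos.append(f[5])
        allele_rows.append(f[6:])
    alleles = np.asarray(allele_rows, dtype=object).reshape(len(sample_ids), m, 2)

    pheno = np.full(len(sample_ids), np.nan)
    for i, p in enumerate(phenos):
        if p == "2":
            pheno[i] = 1.0
        elif p == "1":
            pheno[i] = 0.0
    keep = np.isfinite(pheno)
    if (~keep).any():
        log.append(("individuals_dropped_missing_phenotype", int((~keep).sum())))
    alleles = alleles[keep]
    sample_ids = np.asarray(sample_ids, dtype=object)[keep]
    pheno = pheno[keep]

    code_cols, meta = [], []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        res = _dosage_from_alleles(alleles[:, j, :], snp_id, log)
        if res is None:
            continue
        codes, pair = res
        code_cols.append(codes)
        meta.append((chrom, snp_id, pos, pair))
    order = _sort_snps([r[0] for r in meta], [r[2] for r in meta])
    gm = GenotypeMatrix(
        codes=np.column_stack([code_cols[k] for k in order]),
        snp_ids=np.array([meta[k][1] for k in order], dtype=object),
        chrom=np.array([meta[k][0] for k in order], dtype=object),
        pos_bp=np.array([meta[k][2] for k in order], dtype=np.int64),
        alleles=np.array([meta[k][3] for k in order], dtype=object),
    )
    source = {"ped": str(ped_path), "map": str(map_path),
              "format": "ped", "checksum": _checksum(ped_path)}
    return DatasetBundle(gm, PhenotypeVector(pheno), sample_ids, source, log)


def write_ped_map(bundle_or_rep, ped_path: str | Path, map_path: str | Path) -> None:
    """Write genotypes + phenotype as a PLINK text fileset."""
    gm, y, ids = _unpack(bundle_or_rep)
    with open(map_path, "w") as fh:
        for j in range(gm.n_snps):
            fh.write(f"{gm.chrom[j]}\t{gm.snp_ids[j]}\t0\t{gm.pos_bp[j]}\n")
    with open(ped_path, "w") as fh:
        for i in range(gm.n_individuals):
            status = "2" if y.values[i] == 1 else "1"
            fields = [f"F{i + 1}", str(ids[i]), "0", "0", "0", status]
            for j in range(gm.n_snps):
                c = gm.codes[i, j]
                minor, major = gm.alleles[j]
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [minor] * int(c) + [major] * int(2 - c)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path: str | Path, phenotype_path: str | Path) -> DatasetBundle:
    """Load genotypes from a VCF (GT field) plus a sample/status TSV.

    Status column: 1 = case, 0 = control.  Multiallelic records are
    skipped with a log entry; './.' becomes missing.
    """
    from cyvcf2 import VCF

    log: list = []
    pheno_map: dict[str, float] = {}
    for ln, line in enumerate(Path(phenotype_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 2:
            raise ParseError(f"{phenotype_path}:{ln}: expected 'sample<TAB>status'")
        pheno_map[f[0]] = float(f[1])

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing_pheno = [s for s in samples if s not in pheno_map]
    unknown = sorted(set(pheno_map) - set(samples))
    if unknown:
        raise ParseError(f"phenotype samples absent from VCF: {unknown}")

    rows, meta = [], []
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.ALT[0] not in ("A", "C", "G", "T") \
                or len(rec.REF) != 1:
            log.append(("record_skipped_not_biallelic_snp", f"{rec.CHROM}:{rec.POS}"))
            continue
        gt = rec.genotype.array()[:, :2]
        alt_dosage = np.where((gt < 0).any(axis=1), MISSING,
                              gt.clip(min=0).sum(axis=1)).astype(np.int8)
        rows.append(alt_dosage)
        meta.append((rec.CHROM, rec.ID or f"{rec.CHROM}:{rec.POS}", rec.POS,
                     rec.REF, rec.ALT[0]))
    if not rows:
        raise ParseError(f"{vcf_path}: no usable biallelic SNP records")

    keep = np.array([s in pheno_map and np.isfinite(pheno_map[s]) for s in samples])
    if missing_pheno:
        log.append(("individuals_dropped_missing_phenotype", len(missing_pheno)))
    codes_alt = np.stack(rows, axis=1)[keep]      # N x M alt dosage
    sample_ids = np.asarray(samples, dtype=object)[keep]
    pheno = np.array([pheno_map[s] for s in sample_ids])

    # recode to minor-allele dosage, dataset-wide
    codes = np.full_like(codes_alt, MISSING)
    alleles = []
    for j in range(codes_alt.shape[1]):
        col = codes_alt[:, j]
        called = col != MISSING
        ref, alt = meta[j][3], meta[j][4]
        alt_freq = col[called].sum() / (2.0 * max(called.sum(), 1))
        if alt_freq < 0.5 or (alt_freq == 0.5 and alt < ref):
            minor, major = alt, ref
            codes[:, j] = np.where(called, col, MISSING)
        else:
            minor, major = ref, alt
            codes[:, j] = np.where(called, 2 - col, MISSING)
        alleles.append((minor, major))

    order = _sort_snps([r[0] for r in meta], [r[2] for r in meta])
    gm = GenotypeMatrix(
        codes=codes[:, order],
        snp_ids=np.array([meta[k][1] for k in order], dtype=object),
        chrom=np.array([meta[k][0] for k in order], dtype=object),
        pos_bp=np.array([meta[k][2] for k in order], dtype=np.int64),
        alleles=np.array([alleles[k] for k in order], dtype=object),
    )
    source = {"vcf": str(vcf_path), "phenotype": str(phenotype_path),
              "format": "vcf", "checksum": _checksum(vcf_path)}
    return DatasetBundle(gm, PhenotypeVector(pheno), sample_ids, source, log)


def write_vcf(bundle_or_rep, vcf_path: str | Path,
              phenotype_path: str | Path | None = None) -> None:
    """Write genotypes as a minimal GT-only VCF 4.2 (+ phenotype TSV)."""
    gm, y, ids = _unpack(bundle_or_rep)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in ids) + "\n")
        for j in range(gm.n_snps):
            minor, major = gm.alleles[j]
            ref, alt = major, minor          # ALT carries the minor allele
            gts = []
            for c in gm.codes[:, j]:
                gts.append("./." if c == MISSING
                           else ["0/0", "0/1", "1/1"][int(c)])
            fh.write(f"{gm.chrom[j]}\t{gm.pos_bp[j]}\t{gm.snp_ids[j]}\t"
                     f"{_vcf_base(ref)}\t{_vcf_base(alt)}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    if phenotype_path is not None:
        with open(phenotype_path, "w") as fh:
            for s, v in zip(ids, y.values):
                fh.write(f"{s}\t{int(v)}\n")


def _vcf_base(a: str) -> str:
    return a if a in ("A", "C", "G", "T") else "N"


def _unpack(obj):
    """Accept a DatasetBundle or a SimReplicate."""
    if isinstance(obj, DatasetBundle):
        return obj.genotypes, obj.phenotype, obj.sample_ids
    gm = obj.genotypes
    ids = np.array([f"ind{i + 1}" for i in range(gm.n_individuals)], dtype=object)
    return gm, obj.phenotype, ids


def write_truth_manifest(rep, spec, path: str | Path) -> None:
    """TSV of corrupted SNPs: snp_id, model id, error fraction."""
    gm = rep.genotypes
    with open(path, "w") as fh:
        fh.write("snp_id\tsnp_index\tmodel_id\tfraction\n")
        for i in rep.truth_error_snps:
            fh.write(f"{gm.snp_ids[i]}\t{i}\t{spec.model_id}\t"
                     f"{spec.effective_fraction}\n")
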
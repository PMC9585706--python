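"""Readers and writers for the pipeline's tabular and genomic formats.

Conventions: internal coordinates are 0-based half-open (BEDPE-native); VCF
ingestion converts from 1-based. Readers reject malformed coordinates rather
than coercing them, and always report skip counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .tdp import StructuralVariant

logger = logging.getLogger(__name__)

BEDPE_COLUMNS = (
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "svtype",
)


@dataclass
class SnvReadResult:
    snvs: list  # (chrom, pos0, ref, alt)
    n_skipped: int


def read_snvs(path, fmt: str | None = None) -> SnvReadResult:
    """Read SNVs from a VCF 4.2 or a TSV with chrom/pos/ref/alt columns.

    VCF positions (1-based) convert to 0-based; multi-allelic records split
    into one candidate per ALT; non-SNV alleles are skipped and counted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in (".vcf", ".gz") else "tsv"
    if fmt == "vcf":
        return _read_snvs_vcf(path)
    if fmt == "tsv":
        return _read_snvs_tsv(path)
    raise ValueError(f"unknown SNV format {fmt!r}")


def _read_snvs_vcf(path: Path) -> SnvReadResult:
    from cyvcf2 import VCF

    snvs, skipped = [], 0
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if len(rec.REF) == 1 and len(alt) == 1 and alt in "ACGT" and rec.REF in "ACGT":
                snvs.append((rec.CHROM, rec.POS - 1, rec.REF, alt))
            else:
                skipped += 1
    if skipped:
        logger.info("read_snvs(%s): skipped %d non-SNV allele(s)", path, skipped)
    return SnvReadResult(snvs=snvs, n_skipped=skipped)


def _read_snvs_tsv(path: Path) -> SnvReadResult:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"SNV TSV must have columns {sorted(required)}")
    snvs, skipped = [], 0
    for r in df.itertuples():
        ref, alt = str(r.ref), str(r.alt)
        if len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT":
            snvs.append((str(r.chrom), int(r.pos), ref, alt))
        else:
            skipped += 1
    return SnvReadResult(snvs=snvs, n_skipped=skipped)


def write_snvs_vcf(snvs, path) -> None:
    """Write (chrom, pos0, ref, alt) records as a minimal VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt in snvs:
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def read_bedpe(path, sample_id: str = "sample") -> tuple[list[StructuralVariant], int]:
    """Read a BEDPE file (>= 10 columns, 0-based half-open) into SV records.

    Records with start >= end on either side, or interchromosomal events typed
    as intrachromosomal SV classes, are rejected and counted.
    """
    svs, skipped = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}:{lineno}: BEDPE needs >= 10 columns")
            chrom1, start1, end1, chrom2, start2, end2 = parts[:6]
            svtype = parts[10] if len(parts) > 10 else parts[6]
            try:
                start1, end1, start2, end2 = int(start1), int(end1), int(start2), int(end2)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from e
            if start1 >= end1 or start2 >= end2:
                logger.warning("%s:%d: rejected record with start >= end", path, lineno)
                skipped += 1
                continue
            try:
                svs.append(
                    StructuralVariant(
                        sample_id=sample_id,
                        chrom1=chrom1,
                        pos1=start1,
                        chrom2=chrom2,
                        pos2=start2,
                        sv_type=svtype,
                    )
                )
            except ValueError as e:
                logger.warning("%s:%d: rejected (%s)", path, lineno, e)
                skipped += 1
    return svs, skipped


def write_bedpe(svs, path) -> None:
    """Write SV records (StructuralVariant or table rows) as BEDPE."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        for sv in svs:
            fh.write(
                "\t".join(
                    map(
                        str,
                        (
                            sv.chrom1, sv.pos1, sv.pos1 + 1,
                            sv.chrom2, sv.pos2, sv.pos2 + 1,
                            sv.sample_id, ".", "+", "-", sv.sv_type,
                        ),
                    )
                )
                + "\n"
            )


def sv_table_to_records(table: pd.DataFrame) -> list[StructuralVariant]:
    return [
        StructuralVariant(
            sample_id=str(r.sample_id),
            chrom1=str(r.chrom1),
            pos1=int(r.pos1),
            chrom2=str(r.chrom2),
            pos2=int(r.pos2),
            sv_type=str(r.sv_type),
        )
        for r in table.itertuples()
    ]


def write_cohort_tables(tables, out_dir) -> dict[str, Path]:
    """Serialise a synthetic cohort to TSV/BEDPE files in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("samples", "mutations", "methylation", "meth_expression", "outcomes", "pdx_volumes"):
        p = out_dir / f"{name}.tsv"
        getattr(tables, name).to_csv(p, sep="\t", index=False)
        paths[name] = p
    for name in ("spectra", "immune"):
        p = out_dir / f"{name}.tsv"
        getattr(tables, name).to_csv(p, sep="\t", index_label="sample_id")
        paths[name] = p
    p = out_dir / "expression.tsv"
    tables.expression.to_csv(p, sep="\t", index_label="gene")
    paths["expression"] = p
    p = out_dir / "svs.bedpe"
    with open(p, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        for r in tables.svs.itertuples():
            fh.write(
                "\t".join(
                    map(
                        str,
                        (
                            r.chrom1, r.pos1, r.pos1 + 1, r.chrom2, r.pos2, r.pos2 + 1,
                            r.sample_id, ".", "+", "-", r.sv_type,
                        ),
                    )
                )
                + "\n"
            )
    paths["svs"] = p
    return paths


class DictContextProvider:
    """Trinucleotide context lookup backed by an in-memory mapping
    ``{(chrom, pos0): 3-mer}`` — convenient for tests and synthetic data."""

    def __init__(self, contexts: dict):
        self._contexts = contexts

    def __call__(self, chrom: str, pos: int) -> str:
        return self._contexts[(chrom, pos)]


class FastaContextProvider:
    """Trinucleotide context lookup from an indexed FASTA reference."""

    def __init__(self, fasta_path):
        from pyfaidx import Fasta

        self._fasta = Fasta(str(fasta_path))

    def __call__(self, chrom: str, pos: int) -> str:
        seq = self._fasta[chrom][pos - 1 : pos + 2].seq.upper()
        if len(seq) != 3 or any(b not in "ACGT" for b in seq):
            raise KeyError(f"no valid context at {chrom}:{pos}")
        return seq
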
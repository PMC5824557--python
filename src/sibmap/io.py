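"""Readers and writers: genotype tables (TSV/VCF), similarity-hit tables,
map TSVs, block tables/BED and stats JSON.

Genotype TSV layout: ``locus_id  contig_id  mother  father  <offspring...>``
with genotypes written ``a/b`` and missing calls ``./.``. The VCF path maps
allele labels onto nucleotide sequences (labels are not preserved across a
VCF round-trip; genotype structure is).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import FamilyData, MarkerGenotypes
from .linkmap import GeneticMap
from .simdata import HIT_COLUMNS

logger = logging.getLogger("sibmap")

_MISSING_GT = "./."


# ---------------------------------------------------------------------------
# genotype TSV

def write_genotypes_tsv(family: FamilyData, path) -> None:
    rows = []
    for m in family:
        row = {
            "locus_id": m.locus_id,
            "contig_id": m.contig_id,
            "mother": "/".join(m.mother),
            "father": "/".join(m.father),
        }
        for oid, c in zip(family.offspring_ids, m.calls):
            row[oid] = _MISSING_GT if c is None else "/".join(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_gt(s: str):
    if s in (_MISSING_GT, ".", "-", ""):
        return None
    return tuple(s.split("/"))


def read_genotypes_tsv(path, family_id: str = "family") -> FamilyData:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["locus_id", "contig_id", "mother", "father"]
    for col in fixed:
        if col not in df.columns:
            raise ValueError(f"genotype TSV missing column {col!r}")
    offspring = [c for c in df.columns if c not in fixed]
    fam = FamilyData(family_id, offspring)
    for _, row in df.iterrows():
        calls = [_parse_gt(row[o]) for o in offspring]
        fam.add(MarkerGenotypes(
            row["locus_id"], row["contig_id"], family_id,
            _parse_gt(row["mother"]), _parse_gt(row["father"]), calls,
        ))
    return fam


# ---------------------------------------------------------------------------
# genotype VCF (via pysam)

_NUCS = ["A", "C", "G", "T", "AA", "CC", "GG", "TT"]


def write_genotypes_vcf(family: FamilyData, path, mother: str = "mother",
                        father: str = "father") -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    contigs = sorted({m.contig_id for m in family})
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    samples = [mother, father] + list(family.offspring_ids)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    pos_on: dict = {}
    for m in family:
        alleles = sorted(set(m.mother) | set(m.father))
        code = {a: i for i, a in enumerate(alleles)}
        ref = _NUCS[0]
        alts = [_NUCS[i] for i in range(1, len(alleles))]
        pos_on[m.contig_id] = pos_on.get(m.contig_id, 0) + 100
        gts = []
        for g in [m.mother, m.father] + list(m.calls):
            if g is None:
                gts.append(_MISSING_GT)
            else:
                gts.append("/".join(str(code[a]) for a in sorted(g, key=lambda a: code[a])))
        lines.append("\t".join([
            m.contig_id, str(pos_on[m.contig_id]), m.locus_id, ref,
            ",".join(alts) if alts else ".", ".", "PASS", ".", "GT", *gts,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_vcf(path, mother: str, father: str,
                       family_id: str = "family") -> FamilyData:
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    for s in (mother, father):
        if s not in samples:
            raise ValueError(f"unknown sample name {s!r}; VCF has {samples}")
    offspring = [s for s in samples if s not in (mother, father)]
    fam = FamilyData(family_id, offspring)
    for rec in vf:
        alleles = [rec.ref] + list(rec.alts or [])

        def gt(sample):
            g = rec.samples[sample].get("GT")
            if g is None or any(a is None for a in g):
                return None
            return tuple(sorted(alleles[a] for a in g))

        mo, fa = gt(mother), gt(father)
        if mo is None or fa is None:
            logger.warning("locus %s: missing parent genotype, skipped", rec.id)
            continue
        calls = [gt(o) for o in offspring]
        fam.add(MarkerGenotypes(rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom,
                                family_id, mo, fa, calls))
    return fam


def read_genotypes(path, fmt: str = "tsv", mother: str = "mother",
                   father: str = "father", family_id: str = "family") -> FamilyData:
    if fmt == "tsv":
        return read_genotypes_tsv(path, family_id)
    if fmt == "vcf":
        return read_genotypes_vcf(path, mother, father, family_id)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# similarity hits (12-column tabular)

_HIT_TYPES = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}


def read_hits(path) -> pd.DataFrame:
    """Read a 12-column tabular similarity-hit file; malformed rows are
    skipped (count logged). ``sstart > send`` marks a minus-strand hit and
    is preserved as-is (normalization happens at anchor assignment)."""
    rows, bad = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                bad += 1
                continue
            try:
                rec = [parts[0], parts[1]] + [
                    _HIT_TYPES[c](v) for c, v in zip(HIT_COLUMNS[2:], parts[2:])
                ]
            except ValueError:
                bad += 1
                continue
            rows.append(rec)
    if bad:
        logger.warning("%s: skipped %d malformed hit rows", path, bad)
    if not rows:
        logger.warning("%s: empty hit table", path)
        df = pd.DataFrame(columns=HIT_COLUMNS)
    else:
        df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    df.attrs["malformed_rows"] = bad
    return df


def write_hits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# maps, blocks, stats

def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "lg": str})
    return GeneticMap.from_frame(df)


def blocks_to_frame(blocks: list) -> pd.DataFrame:
    rows = [
        (b.block_id, b.lg, b.genome_id, b.chromosome, b.n_loci,
         ",".join(b.locus_ids), round(b.cm_start, 4), round(b.cm_end, 4),
         b.bp_min, b.bp_max, b.orientation)
        for b in blocks
    ]
    return pd.DataFrame(rows, columns=[
        "block_id", "lg", "genome_id", "chromosome", "n_loci", "locus_ids",
        "cm_start", "cm_end", "bp_min", "bp_max", "orientation",
    ])


def write_blocks(blocks: list, path) -> None:
    blocks_to_frame(blocks).to_csv(path, sep="\t", index=False)


def write_blocks_bed(blocks: list, path) -> None:
    """Blocks in genome coordinates, BED (0-based half-open)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chromosome}\t{b.bp_min - 1}\t{b.bp_max}\t"
                     f"{b.block_id}\t{b.n_loci}\t{b.orientation}\n")


def stats_to_frame(stats: list) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


def write_stats_json(stats: list, path, extra: dict | None = None) -> None:
    payload = {"genomes": [s.__dict__ for s in stats]}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
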
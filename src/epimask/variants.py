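"""Cohort-level consensus variants from per-sample VCFs.

Per-sample germline VCFs are merged into a single consensus set of sites:
only PASS records are retained, identical (chrom, pos, ref, alt) records are
pooled by summing allele counts, and the cohort minor-allele frequency (MAF)
is the maximum folded per-alt frequency.  Missing genotypes reduce the total
allele number rather than counting as reference, matching standard AF
semantics.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

# bijective contig renaming between UCSC ("chr1", "chrM") and NCBI ("1", "MT")
_UCSC_TO_NCBI = {f"chr{i}": str(i) for i in range(1, 23)} | {
    "chrX": "X",
    "chrY": "Y",
    "chrM": "MT",
}
_NCBI_TO_UCSC = {v: k for k, v in _UCSC_TO_NCBI.items()}


class DuplicateSampleError(ValueError):
    """The same sample id appears in more than one input VCF."""


class UndefinedFrequencyError(ZeroDivisionError):
    """MAF requested for a site with no called alleles."""


@dataclass(frozen=True)
class ConsensusVariant:
    """A cohort-level variant with reference span and allele counts.

    ``span`` is the 1-based inclusive reference interval the variant
    occupies: length 1 for an SNV, length-of-ref for an indel.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    ac: tuple[int, ...]  # per-alt allele count over the cohort
    an: int  # total called alleles

    @property
    def span(self) -> tuple[int, int]:
        return (self.pos, self.pos + len(self.ref) - 1)

    @property
    def vclass(self) -> str:
        if len(self.ref) != 1 or any(len(a) != 1 for a in self.alts):
            return "indel"
        return "SNV"

    @property
    def maf(self) -> float:
        return compute_maf(self)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alts)


def compute_maf(v: ConsensusVariant) -> float:
    """Maximum folded per-alt minor-allele frequency, in [0, 0.5]."""
    if v.an <= 0:
        raise UndefinedFrequencyError(f"no called alleles at {v.chrom}:{v.pos}")
    best = 0.0
    for ac in v.ac:
        f = ac / v.an
        best = max(best, min(f, 1.0 - f))
    return best


def build_consensus_variants(vcf_paths: Sequence[str | Path]) -> list[ConsensusVariant]:
    """Merge per-sample VCFs into a consensus variant list.

    Only records with FILTER PASS (or ".") are kept.  Identical
    (chrom, pos, ref, alts) records across files are merged by summing ac
    and an.  Sample ids must not repeat across files.
    """
    seen_samples: set[str] = set()
    merged: dict[tuple, ConsensusVariant] = {}
    n_skipped = 0
    for path in vcf_paths:
        vcf = VCF(str(path))
        dupes = seen_samples.intersection(vcf.samples)
        if dupes:
            raise DuplicateSampleError(f"sample id(s) {sorted(dupes)} repeated in {path}")
        seen_samples.update(vcf.samples)
        for rec in vcf:
            # cyvcf2 reports PASS as None; "." comes through as None as well
            if rec.FILTER is not None:
                continue
            try:
                v = _variant_from_record(rec)
            except Exception:  # malformed record: skip, count
                n_skipped += 1
                continue
            if v is None:
                continue
            prev = merged.get(v.key)
            if prev is None:
                merged[v.key] = v
            else:
                merged[v.key] = replace(
                    prev,
                    ac=tuple(a + b for a, b in zip(prev.ac, v.ac)),
                    an=prev.an + v.an,
                )
        vcf.close()
    if n_skipped:
        logger.warning("skipped %d malformed VCF records", n_skipped)
    out = sorted(merged.values(), key=lambda v: (v.chrom, v.pos, v.ref, v.alts))
    logger.info("consensus over %d files: %d variants", len(vcf_paths), len(out))
    return out


def _variant_from_record(rec) -> ConsensusVariant | None:
    alts = tuple(rec.ALT)
    if not alts:
        return None
    # tally called alleles from genotypes; missing alleles shrink an
    ac = [0] * len(alts)
    an = 0
    for gt in rec.genotypes:
        for allele in gt[:-1]:  # last slot is phasing flag
            if allele is None or allele < 0:
                continue
            an += 1
            if allele >= 1:
                ac[allele - 1] += 1
    return ConsensusVariant(
        chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alts=alts, ac=tuple(ac), an=an
    )


def normalize_chromosomes(
    variants: Iterable[ConsensusVariant], style: str
) -> tuple[list[ConsensusVariant], list[str]]:
    """Rename contigs to one naming style ('ncbi' or 'ucsc'); idempotent.

    Returns the renamed variants plus a rejects list of contigs that are in
    neither vocabulary (those variants are passed through unchanged, never
    silently dropped).
    """
    if style not in ("ncbi", "ucsc"):
        raise ValueError(f"style must be 'ncbi' or 'ucsc', got {style!r}")
    table = _UCSC_TO_NCBI if style == "ncbi" else _NCBI_TO_UCSC
    already = set(table.values())
    out: list[ConsensusVariant] = []
    rejects: list[str] = []
    for v in variants:
        if v.chrom in already:
            out.append(v)
        elif v.chrom in table:
            out.append(replace(v, chrom=table[v.chrom]))
        else:
            rejects.append(v.chrom)
            out.append(v)
    if rejects:
        logger.warning("unrecognised contig(s): %s", sorted(set(rejects)))
    return out, sorted(set(rejects))


def write_consensus_tsv(variants: Sequence[ConsensusVariant], path: str | Path) -> None:
    """Sites-only TSV with ac/an/maf columns."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tac\tan\tmaf\tvclass\n")
        for v in variants:
            maf = f"{compute_maf(v):.6g}" if v.an > 0 else "NA"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{','.join(v.alts)}\t"
                f"{','.join(map(str, v.ac))}\t{v.an}\t{maf}\t{v.vclass}\n"
            )


def write_sites_vcf(variants: Sequence[ConsensusVariant], path: str | Path) -> None:
    """Minimal sites-only VCF with AC/AN INFO fields."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"AC={','.join(map(str, v.ac))};AN={v.an}"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t{info}\n")
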
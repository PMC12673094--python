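"""Variant-probe overlap classification and mask construction.

Variants confound Infinium probes in three position classes:

* ``target_cpg``  — the variant's reference span intersects the two-base
  target CpG;
* ``sbe_typeI``   — it intersects the single-base-extension site of a
  Type I probe (for Type II the SBE coincides with the target C, so the
  class is redundant there);
* ``body_within5`` — it intersects probe-body positions within 5 bases of
  the target CpG, excluding positions already in the first two classes.

Overlap uses the variant's full reference span with closed-interval
intersection, so a long deletion can hit all three classes of one probe.
Retained entries must exceed the cohort MAF threshold (strictly > 0.01 by
default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .manifest import NEAR_TARGET_WINDOW, ProbeGeometry, ProbeRecord, compute_probe_geometry
from .variants import ConsensusVariant, compute_maf

logger = logging.getLogger(__name__)

CATEGORIES = ("target_cpg", "sbe_typeI", "body_within5")


class BuildMismatchError(ValueError):
    """Probe and variant inputs are on different genome builds."""


@dataclass(frozen=True)
class MaskEntry:
    """One (probe, variant, category) overlap hit."""

    probe_id: str
    chrom: str
    span: tuple[int, int]
    ref: str
    alts: tuple[str, ...]
    category: str
    maf: float
    vclass: str
    build: str


@dataclass
class Mask:
    """Per-category probe sets plus the retained entries behind them."""

    entries: list[MaskEntry]
    maf_threshold: float
    probes_by_category: dict[str, set[str]] = field(default_factory=dict)

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.probes_by_category.values():
            out |= s
        return out

    def category_counts(self) -> dict[str, dict[str, int]]:
        """Per category: entry counts split by SNV/indel plus unique probes."""
        out: dict[str, dict[str, int]] = {}
        for cat in CATEGORIES:
            hits = [e for e in self.entries if e.category == cat]
            out[cat] = {
                "entries_snv": sum(1 for e in hits if e.vclass == "SNV"),
                "entries_indel": sum(1 for e in hits if e.vclass == "indel"),
                "probes": len(self.probes_by_category.get(cat, set())),
            }
        return out


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Closed-interval intersection on 1-based inclusive coordinates."""
    return a[0] <= b[1] and b[0] <= a[1]


def classify_probe_variant_overlaps(
    probes: Sequence[ProbeRecord],
    variants: Sequence[ConsensusVariant],
    variant_build: str | None = None,
    window: int = NEAR_TARGET_WINDOW,
    geometries: Mapping[str, ProbeGeometry] | None = None,
) -> list[MaskEntry]:
    """Classify every variant-probe overlap into the three position classes.

    A variant may generate entries in multiple categories for the same
    probe.  Inputs must share chromosome naming style; if ``variant_build``
    is given it must match the probes' build.
    """
    if not probes:
        return []
    build = probes[0].build
    if any(p.build != build for p in probes):
        raise BuildMismatchError("probe collection mixes genome builds")
    if variant_build is not None and variant_build != build:
        raise BuildMismatchError(
            f"variants on {variant_build} but probes on {build}; harmonise builds first"
        )

    # index variants per chromosome, sorted by span start, for windowed scan
    by_chrom: dict[str, list[ConsensusVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for vs in by_chrom.values():
        vs.sort(key=lambda v: v.span)

    entries: list[MaskEntry] = []
    for p in probes:
        geom = geometries[p.probe_id] if geometries else compute_probe_geometry(p, window=window)
        lo = min(geom.body_interval[0], geom.target_interval[0], geom.sbe_interval[0])
        hi = max(geom.body_interval[1], geom.target_interval[1], geom.sbe_interval[1])
        for v in by_chrom.get(p.chrom, ()):
            span = v.span
            if span[1] < lo or span[0] > hi:
                continue
            maf = compute_maf(v) if v.an > 0 else 0.0
            common = dict(
                probe_id=p.probe_id, chrom=v.chrom, span=span, ref=v.ref, alts=v.alts,
                maf=maf, vclass=v.vclass, build=build,
            )
            if _intervals_overlap(span, geom.target_interval):
                entries.append(MaskEntry(category="target_cpg", **common))
            if p.design_type == "I" and _intervals_overlap(span, geom.sbe_interval):
                entries.append(MaskEntry(category="sbe_typeI", **common))
            if any(_intervals_overlap(span, piece) for piece in geom.near_target_body):
                entries.append(MaskEntry(category="body_within5", **common))
    logger.info("classified %d overlap entries over %d probes", len(entries), len(probes))
    return entries


def build_mask(entries: Iterable[MaskEntry], maf_threshold: float = 0.01,
               strict: bool = True) -> Mask:
    """Apply the MAF rule and collect per-category probe sets.

    ``strict=True`` keeps entries with maf strictly greater than the
    threshold (the default rule); ``strict=False`` uses >=.
    """
    if maf_threshold < 0:
        raise ValueError(f"maf_threshold must be non-negative, got {maf_threshold}")
    keep = [
        e for e in entries
        if (e.maf > maf_threshold if strict else e.maf >= maf_threshold)
    ]
    by_cat: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    for e in keep:
        by_cat[e.category].add(e.probe_id)
    return Mask(entries=keep, maf_threshold=maf_threshold, probes_by_category=by_cat)


def summarize_mask_composition(
    mask: Mask,
    probes: Sequence[ProbeRecord],
    enhancer_probe_ids: set[str] | None = None,
) -> dict:
    """Composition of the masked-probe union over manifest facets.

    Percentages are relative to the total number of masked probes on the
    platform.  ``enhancer_probe_ids`` optionally marks probes overlapping an
    enhancer track (computed upstream by the annotation module).
    """
    by_id = {p.probe_id: p for p in probes}
    masked = sorted(mask.union)
    absent = [pid for pid in masked if pid not in by_id]
    if absent:
        raise KeyError(f"masked probe(s) missing from probe table: {absent[:5]}")

    n = len(masked)
    summary: dict = {
        "n_masked_probes": n,
        "zero_denominator": n == 0,
        "category_counts": mask.category_counts(),
        "maf_threshold": mask.maf_threshold,
    }
    facets = {
        "gene_region": lambda p: p.gene_region,
        "island_relation": lambda p: p.island_relation,
        "design_type": lambda p: p.design_type,
    }
    for facet, getter in facets.items():
        counts: dict[str, int] = {}
        for pid in masked:
            label = getter(by_id[pid])
            counts[label] = counts.get(label, 0) + 1
        summary[facet] = {
            lab: {"count": c, "percent": 100.0 * c / n if n else 0.0}
            for lab, c in sorted(counts.items())
        }
    if enhancer_probe_ids is not None:
        hit = sum(1 for pid in masked if pid in enhancer_probe_ids)
        summary["enhancer_overlap"] = {
            "count": hit,
            "percent": 100.0 * hit / n if n else 0.0,
        }
    return summary


def mask_entries_to_frame(entries: Sequence[MaskEntry]) -> pd.DataFrame:
    rows = [
        {
            "probe_id": e.probe_id, "chrom": e.chrom, "start": e.span[0], "end": e.span[1],
            "ref": e.ref, "alt": ",".join(e.alts), "maf": e.maf, "vclass": e.vclass,
            "category": e.category, "build": e.build,
        }
        for e in entries
    ]
    cols = ["probe_id", "chrom", "start", "end", "ref", "alt", "maf", "vclass", "category", "build"]
    return pd.DataFrame(rows, columns=cols)


def write_mask_outputs(mask: Mask, probes: Sequence[ProbeRecord], outdir) -> None:
    """Per-category TSVs, a union probe list, a BED of masked target
    intervals (0-based half-open) and a JSON composition summary."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = mask_entries_to_frame(mask.entries)
    for cat in CATEGORIES:
        frame[frame["category"] == cat].to_csv(outdir / f"mask_{cat}.tsv", sep="\t", index=False)
    union = sorted(mask.union)
    (outdir / "mask_union_probes.txt").write_text("\n".join(union) + ("\n" if union else ""))
    by_id = {p.probe_id: p for p in probes}
    with open(outdir / "mask_targets.bed", "w") as fh:
        for pid in union:
            p = by_id[pid]
            fh.write(f"{p.chrom}\t{p.cpg_pos - 1}\t{p.cpg_pos + 1}\t{pid}\n")
    summary = summarize_mask_composition(mask, probes)
    (outdir / "mask_summary.json").write_text(json.dumps(summary, indent=2))
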
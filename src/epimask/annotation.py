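"""Interval-track annotation of CpG probes and context composition reports.

Tracks (chromatin states, enhancers, repeats, PMDs, arbitrary user BEDs) are
read as 0-based half-open BED and queried with the two-base target CpG of
each probe: a probe is labelled by every interval containing either base of
its CpG.  The nine-state prostate chromatin vocabulary can be rolled up to
coarse classes (five enhancer labels -> "enhancer", three promoter labels ->
"promoter").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .manifest import ProbeRecord

logger = logging.getLogger(__name__)

#: Roll-up of the prostate-tumour chromatin-state vocabulary.
CHROMATIN_ROLLUP = {
    "Active non-prostate lineage enhancer": "enhancer",
    "Active prostate lineage-specific enhancer": "enhancer",
    "Bivalent poised enhancer": "enhancer",
    "Primed non-prostate lineage-specific enhancer": "enhancer",
    "Primed prostate lineage enhancer": "enhancer",
    "Active non-prostate lineage promoter": "promoter",
    "Active prostate lineage-specific promoter": "promoter",
    "Bivalent poised promoter": "promoter",
}


class BuildMismatchError(ValueError):
    pass


@dataclass
class AnnotationTrack:
    """A named interval track on one genome build.

    ``intervals`` holds (chrom, start, end, label) with 1-based inclusive
    coordinates internally; :meth:`from_bed` converts from BED's 0-based
    half-open convention on read.
    """

    name: str
    build: str
    intervals: list[tuple[str, int, int, str]]
    label_vocabulary: set[str] = field(default_factory=set)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for chrom, start, end, label in self.intervals:
            if end < start:
                raise ValueError(f"negative-length interval {chrom}:{start}-{end} in {self.name}")
            self.label_vocabulary.add(label)
            # IntervalTree is half-open; store [start, end] inclusive as [start, end+1)
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, label)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None, build: str = "hg38") -> "AnnotationTrack":
        """Read BED4/BED6 (0-based half-open; converted on read)."""
        path = Path(path)
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                label = parts[3] if len(parts) > 3 else name or path.stem
                intervals.append((chrom, start0 + 1, end0, label))
        logger.info("read %d intervals from %s (BED 0-based half-open convention applied)",
                    len(intervals), path)
        return cls(name=name or path.stem, build=build, intervals=intervals)

    def labels_at(self, chrom: str, start: int, end: int) -> set[str]:
        """All labels of intervals intersecting the 1-based inclusive [start, end]."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end + 1)}


def annotate_probe_contexts(
    probes: Sequence[ProbeRecord],
    tracks: Sequence[AnnotationTrack],
    window: int = 0,
) -> dict[str, dict[str, set[str]]]:
    """Label every probe by every track covering its target CpG.

    Returns {probe_id: {track_name: set-of-labels}}; probes outside a track
    get the sentinel label "none".  ``window`` optionally extends the
    two-base CpG query interval symmetrically.
    """
    for t in tracks:
        for p in probes[:1]:
            if t.build != p.build:
                raise BuildMismatchError(
                    f"track {t.name!r} on {t.build} but probes on {p.build}"
                )
    out: dict[str, dict[str, set[str]]] = {}
    for p in probes:
        start, end = p.cpg_pos - window, p.cpg_pos + 1 + window
        per_track = {}
        for t in tracks:
            labels = t.labels_at(p.chrom, start, end)
            per_track[t.name] = labels if labels else {"none"}
        out[p.probe_id] = per_track
    return out


def context_composition_report(
    probe_set: Iterable[str],
    labels: Mapping[str, Mapping[str, set[str]]],
    rollup: Mapping[str, str] | None = None,
) -> dict:
    """Per-track composition percentages for a probe set.

    For each track (facet), the report counts probes carrying each label;
    multi-label probes count once per label, so a facet with overlapping
    labels is flagged non-exclusive (percentages then exceed 100).  With a
    roll-up map (e.g. :data:`CHROMATIN_ROLLUP`), coarse-class percentages
    are computed alongside the fine labels.
    """
    rollup = rollup if rollup is not None else CHROMATIN_ROLLUP
    probe_set = list(probe_set)
    missing = [pid for pid in probe_set if pid not in labels]
    if missing:
        raise KeyError(f"probe(s) not annotated: {missing[:5]}")
    n = len(probe_set)
    report: dict = {"n_probes": n, "zero_denominator": n == 0, "facets": {}}
    if n == 0:
        return report
    track_names = next(iter(labels.values())).keys()
    for track in track_names:
        counts: dict[str, int] = {}
        roll_counts: dict[str, int] = {}
        total_labels = 0
        for pid in probe_set:
            labs = labels[pid][track]
            total_labels += len(labs)
            rolled = set()
            for lab in labs:
                counts[lab] = counts.get(lab, 0) + 1
                rolled.add(rollup.get(lab, lab))
            for r in rolled:
                roll_counts[r] = roll_counts.get(r, 0) + 1
        report["facets"][track] = {
            "labels": {lab: {"count": c, "percent": 100.0 * c / n}
                       for lab, c in sorted(counts.items())},
            "rollup": {lab: {"count": c, "percent": 100.0 * c / n}
                       for lab, c in sorted(roll_counts.items())},
            "exclusive": total_labels == n,
        }
    return report


def write_probe_annotation_tsv(
    labels: Mapping[str, Mapping[str, set[str]]], path: str | Path
) -> None:
    rows = []
    for pid, per_track in labels.items():
        row = {"probe_id": pid}
        for track, labs in per_track.items():
            row[track] = ";".join(sorted(labs))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
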
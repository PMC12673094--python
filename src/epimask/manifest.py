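"""EPIC-style array manifest parsing and probe geometry.

An Infinium methylation probe interrogates a single CpG dinucleotide.  Its
readout can be corrupted by genetic variation at three classes of position:
the two-base target CpG itself, the single-base-extension (SBE) site of
Type I probes, and the near-target end of the ~50-base hybridisation body.
This module models those positions explicitly so that variant overlap can be
classified downstream.

Coordinates are 1-based inclusive throughout; BED output converts to
0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GENE_REGIONS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "ExonBnd", "3'UTR", "IGR")
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

#: Fixed mapping from manifest strand annotation to the side of the CpG on
#: which the probe body lies along the reference.  Vendor manifests encode
#: strand as F/R (design strand) or TOP/BOT; the table below is this
#: package's documented convention and can be overridden per call.
DEFAULT_STRAND_TO_ORIENTATION = {
    "F": "right",
    "R": "left",
    "TOP": "right",
    "BOT": "left",
    "+": "right",
    "-": "left",
}

#: Column maps per manifest dialect.  Keys are our canonical field names,
#: values the header names used by that dialect.
DIALECTS = {
    "epicv1": {
        "probe_id": "IlmnID",
        "chrom": "CHR",
        "cpg_pos": "MAPINFO",
        "design_type": "Infinium_Design_Type",
        "strand": "Strand",
        "gene_region": "UCSC_RefGene_Group",
        "island_relation": "Relation_to_UCSC_CpG_Island",
    },
    "epicv2": {
        "probe_id": "IlmnID",
        "chrom": "CHR",
        "cpg_pos": "MAPINFO",
        "design_type": "Infinium_Design_Type",
        "strand": "Strand_FR",
        "gene_region": "UCSC_RefGene_Group",
        "island_relation": "Relation_to_UCSC_CpG_Island",
    },
}

DIALECT_BUILD = {"epicv1": "hg19", "epicv2": "hg38"}


class ManifestFormatError(ValueError):
    """A manifest file does not match the declared dialect."""


class ConsistencyError(ValueError):
    """Inputs violate a cross-record invariant."""


@dataclass(frozen=True)
class ProbeRecord:
    """One array probe and its manifest-borne annotation."""

    probe_id: str
    chrom: str
    cpg_pos: int
    design_type: str  # "I" or "II"
    orientation: str  # "left" or "right": side of the CpG holding the body
    build: str  # "hg19" or "hg38"
    gene_region: str = "IGR"
    island_relation: str = "OpenSea"
    probe_len: int = 50

    def __post_init__(self) -> None:
        if self.cpg_pos < 1:
            raise ValueError(f"cpg_pos must be >= 1, got {self.cpg_pos}")
        if self.probe_len < 2:
            raise ValueError(f"probe_len must be >= 2, got {self.probe_len}")
        if self.design_type not in ("I", "II"):
            raise ValueError(f"design_type must be 'I' or 'II', got {self.design_type!r}")
        if self.orientation not in ("left", "right"):
            raise ValueError(f"orientation must be 'left'/'right', got {self.orientation!r}")

    @property
    def base_id(self) -> str:
        """Probe id with any EPICv2 replicate suffix (e.g. ``_TC21``) removed."""
        return strip_replicate_suffix(self.probe_id)

    @property
    def is_cpg_probe(self) -> bool:
        return self.probe_id.startswith("cg")


@dataclass(frozen=True)
class ProbeGeometry:
    """Variant-sensitive intervals of one probe, 1-based inclusive.

    ``near_target_body`` is the list of body sub-intervals within 5 bases of
    the target CpG, excluding the target bases themselves (and, for Type I,
    the SBE base — which never lies in the body anyway).
    """

    target_interval: tuple[int, int]
    sbe_interval: tuple[int, int]
    body_interval: tuple[int, int]
    near_target_body: tuple[tuple[int, int], ...] = field(default_factory=tuple)


NEAR_TARGET_WINDOW = 5  # bases: probe-body positions this close to the CpG confound readout


def strip_replicate_suffix(probe_id: str) -> str:
    """EPICv2 replicate probes share a CpG and differ only in an ``_XXnn`` suffix."""
    return probe_id.split("_", 1)[0]


def compute_probe_geometry(p: ProbeRecord, window: int = NEAR_TARGET_WINDOW) -> ProbeGeometry:
    """Derive the target / SBE / body intervals of a probe.

    Type II chemistry extends at the interrogated C, so the body abuts the
    CpG on the orientation side and the SBE site coincides with the target C.
    Type I chemistry extends at the base adjacent to the CpG: the body covers
    the CpG at its terminus and extends to the orientation side, with the SBE
    base immediately beyond the CpG on the opposite side.
    """
    c = p.cpg_pos
    target = (c, c + 1)
    n = p.probe_len
    if p.design_type == "II":
        # extension happens at the interrogated C: the target base adjacent
        # to the body terminus, so the SBE class is redundant for Type II
        if p.orientation == "left":
            body = (c - n, c - 1)
            sbe = (c, c)
        else:
            body = (c + 2, c + 1 + n)
            sbe = (c + 1, c + 1)
    else:
        if p.orientation == "left":
            body = (c + 1 - (n - 1), c + 1)
            sbe = (c + 2, c + 2)
        else:
            body = (c, c + n - 1)
            sbe = (c - 1, c - 1)

    near = _near_target_intervals(body, target, window)
    return ProbeGeometry(target_interval=target, sbe_interval=sbe, body_interval=body, near_target_body=near)


def _near_target_intervals(
    body: tuple[int, int], target: tuple[int, int], window: int
) -> tuple[tuple[int, int], ...]:
    lo = target[0] - window
    hi = target[1] + window
    # intersect the window with the body, then cut out the target bases
    start = max(body[0], lo)
    end = min(body[1], hi)
    if start > end:
        return ()
    pieces = []
    if start < target[0]:
        pieces.append((start, min(end, target[0] - 1)))
    if end > target[1]:
        pieces.append((max(start, target[1] + 1), end))
    return tuple(pieces)


def _clean_chrom(raw) -> str | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if not s or s in ("nan", "0"):
        return None
    return s if s.startswith("chr") else f"chr{s}"


def parse_manifest(
    path: str | Path,
    dialect: str,
    probe_len: int = 50,
    strand_map: dict[str, str] | None = None,
) -> list[ProbeRecord]:
    """Read an EPIC-style manifest CSV into :class:`ProbeRecord` objects.

    Rows on "chr0"/"chrM" or with a missing position are dropped (and
    counted in the log); non-CpG-context rows (id prefix other than "cg")
    are retained but flagged via :attr:`ProbeRecord.is_cpg_probe`.

    Raises
    ------
    ManifestFormatError
        If a mandatory column of the declared dialect is absent.
    KeyError
        If the dialect is unknown.
    """
    if dialect not in DIALECTS:
        raise KeyError(f"unknown manifest dialect {dialect!r}; known: {sorted(DIALECTS)}")
    colmap = DIALECTS[dialect]
    strand_map = strand_map or DEFAULT_STRAND_TO_ORIENTATION
    # vendor manifests carry descriptive header junk before the [Assay] block;
    # locate the true header line by probing for the id column
    df = _read_manifest_csv(path, colmap["probe_id"])
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ManifestFormatError(
            f"manifest at {path} lacks column(s) {missing} required by dialect {dialect!r}"
        )

    build = DIALECT_BUILD[dialect]
    records: list[ProbeRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        chrom = _clean_chrom(r[colmap["chrom"]])
        pos = r[colmap["cpg_pos"]]
        if chrom is None or chrom in ("chr0", "chrM") or pd.isna(pos):
            n_dropped += 1
            continue
        strand_raw = str(r[colmap["strand"]]).strip().upper()
        if strand_raw not in strand_map:
            raise ManifestFormatError(
                f"unmapped strand value {strand_raw!r} in manifest {path}"
            )
        records.append(
            ProbeRecord(
                probe_id=str(r[colmap["probe_id"]]),
                chrom=chrom,
                cpg_pos=int(pos),
                design_type=str(r[colmap["design_type"]]).strip(),
                orientation=strand_map[strand_raw],
                build=build,
                gene_region=_first_gene_region(r.get(colmap["gene_region"])),
                island_relation=_simplify_island(r.get(colmap["island_relation"])),
                probe_len=probe_len,
            )
        )
    logger.info("parsed %d probes from %s (%d rows dropped)", len(records), path, n_dropped)
    return records


def _read_manifest_csv(path: str | Path, id_col: str) -> pd.DataFrame:
    with open(path) as fh:
        header_line = None
        for i, line in enumerate(fh):
            if line.split(",")[0].strip() == id_col:
                header_line = i
                break
            if i > 100:
                break
    if header_line is None:
        raise ManifestFormatError(f"no header row starting with {id_col!r} found in {path}")
    return pd.read_csv(path, skiprows=header_line, dtype=str, low_memory=False)


def _first_gene_region(raw) -> str:
    if raw is None or pd.isna(raw) or not str(raw).strip():
        return "IGR"
    first = str(raw).split(";")[0].strip()
    return first if first in GENE_REGIONS else "Body"


def _simplify_island(raw) -> str:
    if raw is None or pd.isna(raw) or not str(raw).strip():
        return "OpenSea"
    s = str(raw).split(";")[0].strip()
    if "Island" in s:
        return "Island"
    if "Shore" in s:
        return "Shore"
    if "Shelf" in s:
        return "Shelf"
    return "OpenSea"


def probes_to_frame(records: Iterable[ProbeRecord]) -> pd.DataFrame:
    """Tabulate probe records (one row per probe, indexed by probe_id)."""
    rows = [
        {
            "probe_id": p.probe_id,
            "base_id": p.base_id,
            "chrom": p.chrom,
            "cpg_pos": p.cpg_pos,
            "design_type": p.design_type,
            "orientation": p.orientation,
            "build": p.build,
            "gene_region": p.gene_region,
            "island_relation": p.island_relation,
            "probe_len": p.probe_len,
        }
        for p in records
    ]
    return pd.DataFrame(rows).set_index("probe_id", drop=False) if rows else pd.DataFrame(
        columns=["probe_id", "base_id", "chrom", "cpg_pos", "design_type", "orientation",
                 "build", "gene_region", "island_relation", "probe_len"]
    )


def collapse_replicate_probes(
    records: Sequence[ProbeRecord], betas: pd.DataFrame, how: str = "mean"
) -> pd.DataFrame:
    """Collapse EPICv2 replicate probes of one CpG to a single beta row.

    ``betas`` is probes x samples, indexed by probe_id.  Rows sharing a
    base_id are averaged (``how='mean'``, default) or medianed; the result is
    indexed by base_id.  Replicates of one CpG must agree on coordinates.
    """
    if how not in ("mean", "median"):
        raise ValueError(f"how must be 'mean' or 'median', got {how!r}")
    by_id = {p.probe_id: p for p in records}
    missing = [pid for pid in betas.index if pid not in by_id]
    if missing:
        raise ConsistencyError(f"beta rows without a probe record: {missing[:5]}")

    coords: dict[str, tuple[str, int]] = {}
    for pid in betas.index:
        p = by_id[pid]
        key = (p.chrom, p.cpg_pos)
        prev = coords.setdefault(p.base_id, key)
        if prev != key:
            raise ConsistencyError(
                f"replicate probes of {p.base_id} map to different coordinates: {prev} vs {key}"
            )

    base_ids = pd.Index([by_id[pid].base_id for pid in betas.index], name="base_id")
    grouped = betas.groupby(base_ids)
    collapsed = grouped.mean() if how == "mean" else grouped.median()
    n_collapsed = len(betas) - len(collapsed)
    if n_collapsed:
        logger.info("collapsed %d replicate probe rows into base ids", n_collapsed)
    return collapsed


def target_intervals_to_bed(records: Iterable[ProbeRecord]) -> pd.DataFrame:
    """Target CpG intervals as BED6 (0-based half-open)."""
    rows = [
        {
            "chrom": p.chrom,
            "start": p.cpg_pos - 1,
            "end": p.cpg_pos + 1,
            "name": p.probe_id,
            "score": 0,
            "strand": "+" if p.orientation == "right" else "-",
        }
        for p in records
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
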
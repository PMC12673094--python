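"""End-to-end pipeline driver.

Stages run in a fixed dependency order (simulate -> mask; simulate -> dmp
-> dmr -> enrich); each stage writes its outputs plus a provenance record
(input hashes, config snapshot, seed, package version), and completed
stages are skipped on re-run unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .beta import BetaMatrix
from .config import RunConfig
from .differential import DMRConfig, call_dmrs, dmrs_to_bed, dmrs_to_frame, fit_dmps
from .enrichment import permutation_overlap_test
from .manifest import parse_manifest
from .masking import build_mask, classify_probe_variant_overlaps, write_mask_outputs
from .simulate import SimulationSpec, simulate_beta_cohort, simulate_manifest_and_vcf
from .variants import build_consensus_variants

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "mask", "dmp", "dmr", "enrich"]
STAGE_DEPS = {
    "simulate": [],
    "mask": ["simulate"],
    "dmp": ["simulate"],
    "dmr": ["dmp"],
    "enrich": ["dmp", "dmr"],
}


class DependencyError(RuntimeError):
    pass


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance_path(outdir: Path, stage: str) -> Path:
    return outdir / stage / "provenance.json"


def _write_provenance(outdir: Path, stage: str, cfg: RunConfig, inputs: list[Path]) -> None:
    rec = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "inputs": {str(p): _hash_file(p) for p in inputs if p.exists()},
    }
    _provenance_path(outdir, stage).write_text(json.dumps(rec, indent=2, sort_keys=True))


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None, force: bool = False) -> dict:
    """Execute the requested stages in order; returns a status map.

    Stage dependencies must be satisfied either by inclusion in this run or
    by outputs of a previous run in the same output directory; a missing
    dependency raises :class:`DependencyError` before any work starts.
    """
    stages = stages or STAGE_ORDER
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config_snapshot.yaml")

    for s in stages:
        for dep in STAGE_DEPS[s]:
            if dep not in stages and not _provenance_path(outdir, dep).exists():
                raise DependencyError(f"stage {s!r} requires {dep!r} output; run it first")

    status: dict[str, str] = {}
    for s in stages:
        stage_dir = outdir / s
        if _provenance_path(outdir, s).exists() and not force:
            logger.info("stage %s already complete; skipping (use force to re-run)", s)
            status[s] = "skipped"
            continue
        stage_dir.mkdir(parents=True, exist_ok=True)
        _STAGES[s](cfg, outdir)
        status[s] = "completed"
    return status


def _stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    stage_dir = outdir / "simulate"
    spec = SimulationSpec(
        seed=cfg.seed, n_probes=cfg.sim_n_probes,
        n_dmps=cfg.sim_n_dmps, n_dmrs=cfg.sim_n_dmrs,
    )
    paths = simulate_manifest_and_vcf(spec, stage_dir, dialect=cfg.dialect)
    m, truth = simulate_beta_cohort(spec)
    m.to_tsv(stage_dir / "cohort")
    (stage_dir / "beta_truth.json").write_text(json.dumps(
        {k: v for k, v in truth.items() if k != "dmr_regions"}
        | {"dmr_regions": truth["dmr_regions"]}, indent=2, default=str))
    _write_provenance(outdir, "simulate", cfg, list(paths.values()))


def _stage_mask(cfg: RunConfig, outdir: Path) -> None:
    stage_dir = outdir / "mask"
    manifest = Path(cfg.manifest) if cfg.manifest else outdir / "simulate" / f"manifest_{cfg.dialect}.csv"
    vcf = Path(cfg.vcf) if cfg.vcf else outdir / "simulate" / "cohort.vcf"
    probes = parse_manifest(manifest, cfg.dialect)
    variants = build_consensus_variants([vcf])
    entries = classify_probe_variant_overlaps(probes, variants)
    mask = build_mask(entries, maf_threshold=cfg.maf_threshold)
    write_mask_outputs(mask, probes, stage_dir)
    _write_provenance(outdir, "mask", cfg, [manifest, vcf])


def _load_cohort(cfg: RunConfig, outdir: Path) -> BetaMatrix:
    if cfg.beta:
        return BetaMatrix.from_tsv(cfg.beta, cfg.covariates, cfg.coords)
    prefix = outdir / "simulate" / "cohort"
    return BetaMatrix.from_tsv(f"{prefix}_beta.tsv", f"{prefix}_covariates.tsv",
                               f"{prefix}_coords.tsv")


def _stage_dmp(cfg: RunConfig, outdir: Path) -> None:
    stage_dir = outdir / "dmp"
    m = _load_cohort(cfg, outdir)
    res = fit_dmps(m, group=cfg.group, adjust=cfg.adjust, fdr=cfg.fdr,
                   delta_beta_min=cfg.delta_beta_dmp)
    res.to_csv(stage_dir / "dmps.tsv", sep="\t")
    _write_provenance(outdir, "dmp", cfg, [])


def _stage_dmr(cfg: RunConfig, outdir: Path) -> None:
    stage_dir = outdir / "dmr"
    dmps = pd.read_csv(outdir / "dmp" / "dmps.tsv", sep="\t", index_col=0)
    regions = call_dmrs(dmps, DMRConfig(
        lambda_bp=cfg.dmr_lambda, scale_c=cfg.dmr_scale_c,
        min_cpgs=cfg.dmr_min_cpgs, fdr=cfg.fdr, delta_beta_min=cfg.delta_beta_dmr,
    ))
    dmrs_to_frame(regions).to_csv(stage_dir / "dmrs.tsv", sep="\t", index=False)
    dmrs_to_bed(regions, stage_dir / "dmrs.bed")
    _write_provenance(outdir, "dmr", cfg, [outdir / "dmp" / "dmps.tsv"])


def _stage_enrich(cfg: RunConfig, outdir: Path) -> None:
    """Smoke enrichment: overlap of significant DMPs with DMR-constituent
    CpGs against the tested background, by permutation."""
    stage_dir = outdir / "enrich"
    dmps = pd.read_csv(outdir / "dmp" / "dmps.tsv", sep="\t", index_col=0)
    dmrs = pd.read_csv(outdir / "dmr" / "dmrs.tsv", sep="\t")
    background = list(dmps.index)
    sig = set(dmps.index[dmps["significant"].astype(bool)])
    in_dmr = set()
    if len(dmrs) and {"chrom", "cpg_pos"}.issubset(dmps.columns):
        for _, r in dmrs.iterrows():
            hit = dmps[(dmps["chrom"] == r["chrom"])
                       & (dmps["cpg_pos"] >= r["start"]) & (dmps["cpg_pos"] <= r["end"])]
            in_dmr.update(hit.index)
    result = permutation_overlap_test(sig, in_dmr, background,
                                      n_draws=cfg.permutation_n, seed=cfg.seed)
    (stage_dir / "overlap_test.json").write_text(json.dumps(asdict(result), indent=2))
    _write_provenance(outdir, "enrich", cfg,
                      [outdir / "dmp" / "dmps.tsv", outdir / "dmr" / "dmrs.tsv"])


_STAGES = {
    "simulate": _stage_simulate,
    "mask": _stage_mask,
    "dmp": _stage_dmp,
    "dmr": _stage_dmr,
    "enrich": _stage_enrich,
}
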
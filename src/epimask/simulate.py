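"""Seeded synthetic-data generators.

Everything the toolkit consumes can be generated here with known ground
truth: array manifests in both vendor dialects, cohort VCFs with variants
planted at controlled positions relative to probe geometry and controlled
minor-allele frequencies, beta-value cohorts with planted group effects,
spatially clustered regions, covariate effects and cell-type mixtures, and
near-duplicate replicate sample pairs.

Planting positions are derived from the probe-design rules with arithmetic
written out locally (not by calling the geometry module), so truth tables
stay independent of the code they are used to check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beta import BetaMatrix

logger = logging.getLogger(__name__)

#: MAFs planted around the 0.01 filtering boundary.  With 100 diploid
#: cohort samples (an = 200) every value below is exactly representable as
#: an allele count, so the boundary case maf == 0.01 is exact.
DEFAULT_MAFS = (0.005, 0.01, 0.02, 0.05, 0.2)

OFFSET_CLASSES = ("on_cpg", "on_cpg_2", "sbe", "body_1", "body_5", "body_6",
                  "outside", "indel_body")


@dataclass
class SimulationSpec:
    """Study-condition parameters for the generators.

    Defaults mirror the conditions the statistical machinery is meant to
    operate under: two groups of 20 samples, beta-scale noise sd 0.05,
    planted single-CpG effects of 0.4 and region effects of 0.3 over blocks
    of 8 CpGs spaced 100 bp apart, Dirichlet(5, 3, 1) cell-type weights.
    """

    seed: int = 0
    # manifest / variant plan
    n_probes: int = 200
    typeI_fraction: float = 0.16
    chroms: tuple[str, ...] = ("chr1", "chr2")
    probe_spacing: int = 1000
    probe_len: int = 50
    n_vcf_samples: int = 100
    mafs: tuple[float, ...] = DEFAULT_MAFS
    # beta cohort
    n_per_group: tuple[int, int] = (20, 20)
    noise_sigma: float = 0.05
    n_dmps: int = 0
    dmp_delta: float = 0.4
    n_dmrs: int = 0
    dmr_n_cpgs: int = 8
    dmr_spacing: int = 100
    dmr_delta: float = 0.3
    age_slope: float = 0.0
    n_age_probes: int = 0
    # cell-type mixtures
    cell_types: tuple[str, ...] = ("T-luminal", "stromal", "immune")
    dirichlet_alpha: tuple[float, ...] = (5.0, 3.0, 1.0)

    def __post_init__(self) -> None:
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if not (0 < self.dmp_delta < 1 and 0 < self.dmr_delta < 1):
            raise ValueError("planted deltas must lie in (0, 1)")
        for v in (self.n_probes, self.probe_spacing, self.probe_len):
            if v <= 0:
                raise ValueError("counts and sizes must be positive")


# ---------------------------------------------------------------------------
# manifest + VCF with known mask truth


def _local_geometry(c: int, design: str, orient: str, n: int):
    """Probe intervals by the design rules, written out independently."""
    target = {c, c + 1}
    if design == "II":
        body = range(c - n, c) if orient == "left" else range(c + 2, c + 2 + n)
        sbe = c
    else:
        body = range(c - n + 2, c + 2) if orient == "left" else range(c, c + n)
        sbe = c + 2 if orient == "left" else c - 1
    near = {x for x in body
            if min(abs(x - c), abs(x - (c + 1))) <= 5 and x not in target}
    return target, sbe, set(body), near


def simulate_manifest_and_vcf(spec: SimulationSpec, outdir: str | Path,
                              dialect: str = "epicv1") -> dict[str, Path]:
    """Write a manifest CSV, a cohort VCF and a truth table.

    Probes are laid out on ``spec.chroms`` at fixed spacing, cycling through
    design type and orientation.  Around each of the first probes, variants
    are planted at every geometry-relevant offset class with MAFs straddling
    the 0.01 boundary; the truth table states each variant's expected
    category set and whether it survives the strict MAF rule.
    """
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    probes = []
    per_chrom = int(np.ceil(spec.n_probes / len(spec.chroms)))
    i = 0
    for chrom in spec.chroms:
        for j in range(per_chrom):
            if i >= spec.n_probes:
                break
            design = "I" if rng.random() < spec.typeI_fraction else "II"
            orient = "left" if rng.random() < 0.5 else "right"
            pos = 100_000 + j * spec.probe_spacing
            probes.append({
                "IlmnID": f"cg{i:08d}" + ("_TC21" if dialect == "epicv2" and i % 17 == 0 else ""),
                "CHR": chrom.removeprefix("chr") if dialect == "epicv1" else chrom,
                "MAPINFO": pos,
                "Infinium_Design_Type": design,
                ("Strand" if dialect == "epicv1" else "Strand_FR"): "R" if orient == "left" else "F",
                "UCSC_RefGene_Group": rng.choice(["TSS200", "TSS1500", "Body", "", "5'UTR"]),
                "Relation_to_UCSC_CpG_Island": rng.choice(["Island", "N_Shore", "S_Shelf", ""]),
                "_orient": orient, "_design": design, "_chrom": chrom, "_pos": pos,
            })
            i += 1

    manifest_path = outdir / f"manifest_{dialect}.csv"
    man_df = pd.DataFrame(probes)
    man_df[[c for c in man_df.columns if not c.startswith("_")]].to_csv(
        manifest_path, index=False
    )

    # plant variants at every offset class around every probe
    truth_rows = []
    vcf_records = []
    maf_cycle = 0
    for p in probes:
        c, orient, design, chrom = p["_pos"], p["_orient"], p["_design"], p["_chrom"]
        target, sbe, body, near = _local_geometry(c, design, orient, spec.probe_len)
        side = -1 if orient == "left" else 1
        plant = {
            "on_cpg": (c, 1),
            "on_cpg_2": (c + 1, 1),
            "body_1": (c - 1 if orient == "left" else c + 2, 1),
            "body_5": (c - 5 if orient == "left" else c + 6, 1),
            "body_6": (c - 6 if orient == "left" else c + 7, 1),
            "outside": (c - 20 * side, 1),
            "indel_body": (c - 7 if orient == "left" else c + 4, 4),
        }
        if design == "I":
            # for Type II the SBE coincides with the target C, so a distinct
            # SBE plant would duplicate the on-CpG position
            plant["sbe"] = (sbe, 1)
        for cls, (pos, reflen) in plant.items():
            span = set(range(pos, pos + reflen))
            cats = []
            if span & target:
                cats.append("target_cpg")
            if design == "I" and sbe in span:
                cats.append("sbe_typeI")
            if span & near:
                cats.append("body_within5")
            maf = spec.mafs[maf_cycle % len(spec.mafs)]
            maf_cycle += 1
            truth_rows.append({
                "probe_id": p["IlmnID"], "chrom": chrom, "pos": pos, "ref_len": reflen,
                "offset_class": cls, "maf": maf,
                "expected_categories": ",".join(cats) if cats else "",
                "retained_strict_0.01": maf > 0.01,
            })
            vcf_records.append((chrom, pos, reflen, maf))

    vcf_path = outdir / "cohort.vcf"
    _write_cohort_vcf(vcf_records, vcf_path, n_samples=spec.n_vcf_samples)
    truth_path = outdir / "mask_truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    logger.info("simulated %d probes, %d planted variants", len(probes), len(truth_rows))
    return {"manifest": manifest_path, "vcf": vcf_path, "truth": truth_path}


def _write_cohort_vcf(records, path: Path, n_samples: int) -> None:
    """Multi-sample VCF whose genotypes realise each requested MAF exactly.

    With ``n_samples`` diploid samples the allele number is 2 * n_samples;
    the planted alt count is round(maf * an).  Positions may repeat across
    probes; duplicates are dropped (first wins) to keep the file coherent.
    """
    an = 2 * n_samples
    sample_names = [f"S{i:03d}" for i in range(n_samples)]
    seen = set()
    lines = []
    recs = sorted(records, key=lambda r: (r[0], r[1]))
    for chrom, pos, reflen, maf in recs:
        key = (chrom, pos)
        if key in seen:
            continue
        seen.add(key)
        ref = "A" * reflen if reflen > 1 else "A"
        alt = "A" if reflen > 1 else "G"
        ac = int(round(maf * an))
        gts = []
        remaining = ac
        for _ in range(n_samples):
            if remaining >= 2:
                gts.append("1/1")
                remaining -= 2
            elif remaining == 1:
                gts.append("0/1")
                remaining -= 1
            else:
                gts.append("0/0")
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(r[0] for r in recs):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# beta cohorts with planted effects


def simulate_beta_cohort(spec: SimulationSpec) -> tuple[BetaMatrix, dict]:
    """Generate a two-group beta cohort with known planted effects.

    Baselines are drawn from a bimodal mixture (CGI-like low around 0.15,
    open-sea-like high around 0.85).  Group effects of ``dmp_delta`` are
    added at ``n_dmps`` isolated probes and of ``dmr_delta`` over
    ``n_dmrs`` blocks of ``dmr_n_cpgs`` consecutive CpGs spaced
    ``dmr_spacing`` bp apart; an age effect is added at ``n_age_probes``
    probes.  Gaussian noise (sd ``noise_sigma``) is truncated to [0, 1].

    Returns the matrix and a truth dict with planted probe ids, deltas and
    region spans.
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_per_group
    n_samples = n0 + n1

    # genomic layout: background CpGs widely spaced, DMR blocks tight
    chrom = spec.chroms[0]
    probe_ids, positions = [], []
    pos = 1_000_000
    n_background = spec.n_probes
    dmr_truth = []
    block_starts = []
    if spec.n_dmrs:
        insert_every = max(1, n_background // spec.n_dmrs)
    k = 0
    for i in range(n_background):
        pos += int(rng.integers(2000, 5000))
        probe_ids.append(f"cg{k:08d}")
        positions.append(pos)
        k += 1
        if spec.n_dmrs and (i + 1) % insert_every == 0 and len(block_starts) < spec.n_dmrs:
            pos += 5000  # isolate the block from the background
            block = []
            for j in range(spec.dmr_n_cpgs):
                pid = f"cg{k:08d}"
                probe_ids.append(pid)
                positions.append(pos)
                block.append((pid, pos))
                pos += spec.dmr_spacing
                k += 1
            pos += 5000
            block_starts.append(block)

    n_total = len(probe_ids)
    low = rng.random(n_total) < 0.5
    baseline = np.where(
        low,
        np.clip(rng.normal(0.15, 0.05, n_total), 0.02, 0.45),
        np.clip(rng.normal(0.85, 0.05, n_total), 0.55, 0.98),
    )
    # region blocks behave like CGIs: coherent low baselines with headroom
    # for the planted gain of methylation
    id_to_row = {pid: i for i, pid in enumerate(probe_ids)}
    block_rows = [id_to_row[pid] for blk in block_starts for pid, _ in blk]
    if block_rows:
        baseline[block_rows] = np.clip(
            rng.normal(0.25, 0.05, len(block_rows)), 0.1, 0.4)

    # pick isolated DMP probes from the background (never inside DMR blocks)
    block_ids = {pid for blk in block_starts for pid, _ in blk}
    candidates = [i for i, pid in enumerate(probe_ids) if pid not in block_ids]
    dmp_idx = rng.choice(candidates, size=min(spec.n_dmps, len(candidates)), replace=False) \
        if spec.n_dmps else np.array([], dtype=int)
    dmp_sign = rng.choice([-1.0, 1.0], size=len(dmp_idx))

    age = rng.uniform(50, 80, n_samples)
    group = np.array([0] * n0 + [1] * n1)
    age_idx = rng.choice(candidates, size=min(spec.n_age_probes, len(candidates)),
                         replace=False) if spec.n_age_probes else np.array([], dtype=int)

    mu = np.tile(baseline[:, None], (1, n_samples))
    dmp_shift: dict[str, float] = {}
    for j, s in zip(dmp_idx, dmp_sign):
        shift = s * spec.dmp_delta
        if baseline[j] + shift > 0.98 or baseline[j] + shift < 0.02:
            shift = -shift
        mu[j, group == 1] += shift
        dmp_shift[probe_ids[j]] = float(shift)
    dmr_shift: dict[int, float] = {}
    for bi, blk in enumerate(block_starts):
        rows = [id_to_row[pid] for pid, _ in blk]
        # one coherent direction per block, chosen by the block's headroom
        shift = spec.dmr_delta if baseline[rows].mean() <= 0.5 else -spec.dmr_delta
        for j in rows:
            mu[j, group == 1] += shift
        dmr_shift[bi] = float(shift)
    for j in age_idx:
        mu[j, :] += spec.age_slope * (age - age.mean())

    n_clipped = int(np.sum((mu < 0) | (mu > 1)))
    if n_clipped:
        logger.warning("%d planted means clipped to [0, 1]", n_clipped)
    mu = np.clip(mu, 0.0, 1.0)
    betas = np.clip(mu + rng.normal(0.0, spec.noise_sigma, mu.shape), 0.0, 1.0)

    sample_ids = [f"G0_{i:03d}" for i in range(n0)] + [f"G1_{i:03d}" for i in range(n1)]
    values = pd.DataFrame(betas, index=probe_ids, columns=sample_ids)
    covariates = pd.DataFrame(
        {"group": ["A"] * n0 + ["B"] * n1, "age": age, "platform": "epicv1"},
        index=sample_ids,
    )
    coords = pd.DataFrame({"chrom": chrom, "cpg_pos": positions}, index=probe_ids)
    m = BetaMatrix(values=values, covariates=covariates, coords=coords)

    for bi, blk in enumerate(block_starts):
        dmr_truth.append({
            "region_id": f"true_dmr_{bi}",
            "chrom": chrom,
            "start": blk[0][1],
            "end": blk[-1][1] + 1,
            "probe_ids": [pid for pid, _ in blk],
            "delta": dmr_shift[bi],
        })
    truth = {
        "dmp_probes": dmp_shift,
        "dmr_regions": dmr_truth,
        "age_probes": [probe_ids[j] for j in age_idx],
        "group_levels": ("A", "B"),
        "n_clipped": n_clipped,
    }
    return m, truth


def simulate_replicate_pairs(
    m: BetaMatrix, sigma: float, n_pairs: int | None = None, seed: int = 0
) -> tuple[BetaMatrix, list[tuple[str, str]]]:
    """Duplicate samples with independent truncated beta-scale noise.

    Emulates profiling the same specimens on two array versions.  Returns a
    matrix holding original plus replicate columns (suffix ``_rep``) and the
    pairing manifest.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    samples = list(m.values.columns[: n_pairs or m.n_samples])
    pairs = []
    new_cols = {}
    for s in samples:
        rep = f"{s}_rep"
        noise = rng.normal(0.0, sigma, m.n_probes) if sigma > 0 else 0.0
        new_cols[rep] = np.clip(m.values[s].to_numpy(dtype=float) + noise, 0.0, 1.0)
        pairs.append((s, rep))
    values = pd.concat([m.values, pd.DataFrame(new_cols, index=m.values.index)], axis=1)
    cov = m.covariates
    if not cov.empty:
        rep_cov = cov.loc[samples].copy()
        rep_cov.index = [f"{s}_rep" for s in samples]
        if "platform" in rep_cov.columns:
            rep_cov["platform"] = "epicv2"
        cov = pd.concat([cov, rep_cov])
    return BetaMatrix(values=values, covariates=cov, coords=m.coords), pairs


# ---------------------------------------------------------------------------
# cell-type mixtures


def simulate_mixtures(
    spec: SimulationSpec, n_signature_cpgs: int = 100, n_mixtures: int = 100,
    noise_sigma: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Reference profiles, noisy bulk mixtures and true mixing weights.

    Reference profiles are well-separated beta means per cell type; weights
    are Dirichlet(``spec.dirichlet_alpha``) draws; bulk samples are the
    weighted profile mixtures plus truncated Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    types = list(spec.cell_types)
    cpgs = [f"sig{i:05d}" for i in range(n_signature_cpgs)]
    # each CpG is near-0 in some types and near-1 in others so types separate
    anchor = rng.integers(0, len(types), n_signature_cpgs)
    profiles = np.clip(rng.normal(0.15, 0.05, (n_signature_cpgs, len(types))), 0.02, 0.98)
    for i, a in enumerate(anchor):
        profiles[i, a] = np.clip(rng.normal(0.85, 0.05), 0.02, 0.98)
    ref = pd.DataFrame(profiles, index=cpgs, columns=types)

    weights = rng.dirichlet(spec.dirichlet_alpha, n_mixtures)
    bulk = ref.to_numpy() @ weights.T
    bulk = np.clip(bulk + rng.normal(0.0, noise_sigma, bulk.shape), 0.0, 1.0)
    sample_ids = [f"mix{i:03d}" for i in range(n_mixtures)]
    bulk_df = pd.DataFrame(bulk, index=cpgs, columns=sample_ids)
    w_df = pd.DataFrame(weights, index=sample_ids, columns=types)
    return ref, bulk_df, w_df
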
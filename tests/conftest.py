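import numpy as np
import pandas as pd
import pytest

from epimask.beta import BetaMatrix
from epimask.simulate import SimulationSpec, simulate_beta_cohort


def write_vcf(path, records, samples=("S1",)):
    """Minimal single/multi-sample VCF writer for fixtures.

    records: (chrom, pos, ref, alt, filter, genotypes) with genotypes a list
    of GT strings aligned to ``samples``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=PASS,Description="ok">\n')
        fh.write('##FILTER=<ID=LowQual,Description="bad">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(r[0] for r in records):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, filt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\t{filt}\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path


@pytest.fixture
def small_cohort():
    """40-sample null-plus-effects cohort reused across statistical tests."""
    spec = SimulationSpec(seed=11, n_probes=300, n_dmps=8, n_dmrs=3)
    return simulate_beta_cohort(spec)


@pytest.fixture
def null_cohort():
    spec = SimulationSpec(seed=7, n_probes=400)
    m, truth = simulate_beta_cohort(spec)
    assert not truth["dmp_probes"] and not truth["dmr_regions"]
    return m


def make_matrix(values, group=None, coords=None):
    """Assemble a BetaMatrix from a plain array (probes x samples)."""
    values = np.asarray(values, dtype=float)
    probe_ids = [f"cg{i:06d}" for i in range(values.shape[0])]
    sample_ids = [f"s{i:03d}" for i in range(values.shape[1])]
    cov = pd.DataFrame(index=sample_ids)
    if group is not None:
        cov["group"] = list(group)
    coords_df = pd.DataFrame()
    if coords is not None:
        coords_df = pd.DataFrame(coords, index=probe_ids)
    return BetaMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        covariates=cov,
        coords=coords_df,
    )
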
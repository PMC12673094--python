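"""Context enrichment, permutation overlap testing and concordance checks.

Fisher's exact test compares the context composition of a significant set
against the non-significant remainder of the tested background.  The
permutation overlap test asks whether a discovery set's overlap with a
validation set exceeds what size-matched random draws from the background
produce, with the empirical p the proportion of draws reaching the observed
overlap (no pseudocount by default).  Direction concordance compares the
sign of delta-beta across two analysis arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    facet_label: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # conditional-MLE estimate
    p_value: float  # two-sided, by enumeration of table likelihoods


@dataclass
class OverlapTestResult:
    observed: int
    n_draws: int
    null_mean: float
    null_max: int
    p_value: float
    seed: int


def fisher_context_enrichment(
    sig_set: set[str],
    background: set[str],
    labels: Mapping[str, str | set[str]],
) -> list[ContingencyResult]:
    """Per-label 2x2 Fisher enrichment of a significant set vs background.

    ``labels`` maps feature id -> label (or set of labels).  For each label
    present in the background the table is

        [[sig & label, sig & not-label],
         [nonsig & label, nonsig & not-label]]

    The two-sided p sums hypergeometric probabilities of tables at most as
    likely as the observed one (R ``fisher.test`` semantics); the odds ratio
    is the conditional maximum-likelihood estimate.
    """
    if not sig_set:
        raise ValueError("significant set is empty")
    extra = sig_set - background
    if extra:
        raise ValueError(f"significant features outside background: {sorted(extra)[:5]}")
    nonsig = background - sig_set

    def label_members(lab: str) -> set[str]:
        out = set()
        for fid in background:
            labs = labels.get(fid)
            if labs is None:
                continue
            if isinstance(labs, str):
                if labs == lab:
                    out.add(fid)
            elif lab in labs:
                out.add(fid)
        return out

    all_labels: set[str] = set()
    for fid in background:
        labs = labels.get(fid)
        if labs is None:
            continue
        all_labels.update([labs] if isinstance(labs, str) else labs)

    results = []
    for lab in sorted(all_labels):
        members = label_members(lab)
        a = len(sig_set & members)
        b = len(sig_set - members)
        c = len(nonsig & members)
        d = len(nonsig - members)
        res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        orr = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        results.append(
            ContingencyResult(
                facet_label=lab,
                table=((a, b), (c, d)),
                odds_ratio=float(orr.statistic),
                p_value=float(res.pvalue),
            )
        )
    return results


def permutation_overlap_test(
    discovery_set: set[str],
    validation_set: set[str],
    background: Sequence[str],
    n_draws: int = 10000,
    seed: int = 0,
    pseudocount: bool = False,
) -> OverlapTestResult:
    """Empirical significance of discovery/validation overlap.

    Each draw samples ``len(validation_set)`` features uniformly without
    replacement from the background and records its overlap with the
    discovery set; p is the proportion of draws with overlap >= observed
    (with ``pseudocount=True``, (r+1)/(n+1) so p is never exactly 0).
    """
    background = list(dict.fromkeys(background))
    missing = validation_set - set(background)
    if missing:
        raise ValueError(f"validation features outside background: {sorted(missing)[:5]}")
    if len(validation_set) > len(background):
        raise ValueError("validation set larger than background")
    observed = len(discovery_set & validation_set)

    rng = np.random.default_rng(seed)
    in_discovery = np.fromiter(
        (f in discovery_set for f in background), count=len(background), dtype=bool
    )
    k = len(validation_set)
    nulls = np.empty(n_draws, dtype=np.int64)
    for i in range(n_draws):
        idx = rng.choice(len(background), size=k, replace=False)
        nulls[i] = int(in_discovery[idx].sum())
    r = int((nulls >= observed).sum())
    p = (r + 1) / (n_draws + 1) if pseudocount else r / n_draws
    return OverlapTestResult(
        observed=observed,
        n_draws=n_draws,
        null_mean=float(nulls.mean()),
        null_max=int(nulls.max()),
        p_value=float(p),
        seed=seed,
    )


def region_overlap_keys(
    discovery_regions: pd.DataFrame, validation_regions: pd.DataFrame
) -> tuple[set[int], set[int]]:
    """Indices of regions in either frame overlapping the other by >= 1 bp.

    Frames need chrom/start/end columns (1-based inclusive).  Used to turn
    region lists into matchable sets before concordance or overlap testing.
    """
    hits_d: set[int] = set()
    hits_v: set[int] = set()
    for ci, d in discovery_regions.groupby("chrom"):
        v = validation_regions[validation_regions["chrom"] == ci]
        for i, dr in d.iterrows():
            ov = v[(v["start"] <= dr["end"]) & (v["end"] >= dr["start"])]
            if len(ov):
                hits_d.add(i)
                hits_v.update(ov.index)
    return hits_d, hits_v


def direction_concordance(
    discovery: pd.DataFrame, validation: pd.DataFrame, key: str | None = None
) -> dict:
    """Sign agreement and delta-beta correlation between two analysis arms.

    Both frames carry ``delta_beta``; features are matched on the index (or
    the ``key`` column).  Features with delta_beta == 0 in either arm are
    excluded with a note.  Returns the concordant fraction, Pearson r of the
    paired delta-betas, and the per-feature sign table.
    """
    d = discovery.set_index(key) if key else discovery
    v = validation.set_index(key) if key else validation
    shared = d.index.intersection(v.index)
    if len(shared) == 0:
        raise ValueError("no overlapping features between arms")
    dd = d.loc[shared, "delta_beta"].to_numpy(dtype=float)
    vv = v.loc[shared, "delta_beta"].to_numpy(dtype=float)
    nz = (dd != 0) & (vv != 0)
    n_excluded = int((~nz).sum())
    if n_excluded:
        logger.info("excluded %d features with delta_beta == 0 in one arm", n_excluded)
    dd, vv = dd[nz], vv[nz]
    signs = pd.DataFrame(
        {"delta_discovery": dd, "delta_validation": vv,
         "concordant": np.sign(dd) == np.sign(vv)},
        index=shared[nz],
    )
    frac = float(signs["concordant"].mean()) if len(signs) else np.nan
    if len(dd) >= 3 and np.ptp(dd) > 0 and np.ptp(vv) > 0:
        r = float(stats.pearsonr(dd, vv).statistic)
    else:
        r = np.nan
    return {"concordance": frac, "pearson_r": r, "n_features": int(len(signs)),
            "n_excluded_zero": n_excluded, "signs": signs}


def meth_expr_correlation_filter(
    beta_by_gene: pd.DataFrame,
    expression_by_gene: pd.DataFrame,
    not_covered: set[str] | None = None,
    r_min: float = 0.25,
    fdr: float = 0.05,
    min_expression: float = 2.0,
) -> dict:
    """Expression-support filters for enrichment input genes.

    ``beta_by_gene`` rows are (gene, CpG) pairs indexed by a MultiIndex or a
    plain index of "gene:cpg" strings; columns are samples matched 1:1 with
    ``expression_by_gene`` (genes x samples, log2 scale).  A gene passes the
    correlation filter if any of its CpGs correlates with its expression at
    BH q < fdr and |r| > r_min, or if flagged ``not_covered`` (absent from
    the older 450k array, where no correlation is computable).  The
    expression filter retains genes with mean log2 expression >= 2.
    """
    not_covered = not_covered or set()
    shared_samples = beta_by_gene.columns.intersection(expression_by_gene.columns)
    if len(shared_samples) < 3:
        raise ValueError("need >= 3 paired samples for correlation")

    def split(ix) -> tuple[str, str]:
        if isinstance(ix, tuple):
            return ix
        gene, _, cpg = str(ix).partition(":")
        return gene, cpg

    rows = []
    for ix in beta_by_gene.index:
        gene, cpg = split(ix)
        if gene not in expression_by_gene.index:
            continue
        x = beta_by_gene.loc[[ix], shared_samples].to_numpy(dtype=float).ravel()
        y = expression_by_gene.loc[gene, shared_samples].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            continue
        res = stats.pearsonr(x[ok], y[ok])
        rows.append({"gene": gene, "cpg": cpg, "r": float(res.statistic),
                     "p": float(res.pvalue)})
    pairs = pd.DataFrame(rows, columns=["gene", "cpg", "r", "p"])
    if len(pairs):
        pairs["q"] = benjamini_hochberg(pairs["p"].to_numpy())
        pairs["passes"] = (pairs["q"] < fdr) & (pairs["r"].abs() > r_min)
        correlated = set(pairs.loc[pairs["passes"], "gene"])
    else:
        pairs["q"] = pairs["passes"] = pd.Series(dtype=float)
        correlated = set()
    retained = correlated | not_covered

    expressed = set(
        expression_by_gene.index[
            expression_by_gene[shared_samples].mean(axis=1) >= min_expression
        ]
    )
    return {"retained_genes": retained, "expressed_genes": expressed,
            "pair_table": pairs}
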
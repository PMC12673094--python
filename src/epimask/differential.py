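"""Differential methylation: per-CpG tests, smoothed region calling, and
variance-heterogeneity testing.

DMPs come from ordinary least squares of beta on a binary group indicator
plus covariates, probe by probe (vectorised), with Benjamini-Hochberg FDR
across all tested probes.  The effect size delta-beta is the raw difference
of group mean beta (a covariate-adjusted delta is emitted alongside).

DMRs are called by smoothing squared t-statistics along the genome with a
Gaussian kernel (bandwidth lambda, kernel sd = lambda / C), approximating
the smoothed statistic's null by Satterthwaite moment matching against a
scaled chi-square, BH-adjusting the smoothed p-values, and grouping
consecutive significant CpGs no more than lambda apart into regions of at
least ``min_cpgs`` sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class DMRConfig:
    """Region-calling parameters.

    lambda_bp: smoothing bandwidth in bases (kernel support and the maximum
    within-region CpG gap).  scale_c: bandwidth scaling factor; the Gaussian
    kernel sd is lambda_bp / scale_c.  min_cpgs: minimum constituent CpGs.
    fdr: smoothed-q cutoff.  delta_beta_min: |mean delta-beta| filter.
    """

    lambda_bp: float = 1000.0
    scale_c: float = 2.0
    min_cpgs: int = 5
    fdr: float = 0.05
    delta_beta_min: float = 0.10

    def __post_init__(self) -> None:
        if self.lambda_bp <= 0 or self.scale_c <= 0:
            raise ValueError("lambda_bp and scale_c must be positive")
        if self.min_cpgs < 2:
            raise ValueError("min_cpgs must be >= 2")


@dataclass
class DMRegion:
    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_delta_beta: float
    min_smoothed_q: float
    fisher_p: float
    probe_ids: tuple[str, ...] = field(default_factory=tuple)


def _design_matrix(covariates: pd.DataFrame, group: str, adjust: list[str]):
    """Intercept + binary group (sorted level order: second level coded 1) +
    adjustment covariates (categoricals dummy-coded)."""
    g = covariates[group]
    levels = sorted(g.dropna().unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"group {group!r} must be binary, has levels {levels}")
    cols = {"intercept": np.ones(len(covariates)), "group": (g == levels[1]).astype(float)}
    for name in adjust:
        c = covariates[name]
        if pd.api.types.is_numeric_dtype(c):
            cols[name] = c.astype(float).to_numpy()
        else:
            dummies = pd.get_dummies(c, prefix=name, drop_first=True)
            for dcol in dummies.columns:
                cols[dcol] = dummies[dcol].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=covariates.index)
    return X, levels


def fit_dmps(
    m,
    group: str,
    adjust: list[str] | None = None,
    fdr: float = 0.05,
    delta_beta_min: float = 0.20,
    shrink_var: bool = False,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-probe OLS differential methylation.

    Returns a frame indexed by probe id with delta_beta (raw group-mean
    difference, level2 - level1), adjusted_delta_beta (the group OLS
    coefficient), t, p, q and a significance flag
    (q < fdr and |delta_beta| >= delta_beta_min).  Probes with any missing
    beta or zero residual variance are excluded and flagged in ``.attrs``.

    ``shrink_var=True`` applies a simple empirical-Bayes pooled-prior
    squeeze of the residual variances towards their cohort mean with
    ``prior_df`` pseudo-degrees of freedom.
    """
    adjust = adjust or []
    cov = m.covariates
    keep = cov[[group] + adjust].notna().all(axis=1)
    if (~keep).any():
        logger.info("dropping %d samples with missing covariates", int((~keep).sum()))
    samples = cov.index[keep]
    X, levels = _design_matrix(cov.loc[samples], group, adjust)
    g = X["group"].to_numpy()
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("each group level needs at least 2 samples")

    vals = m.values[samples]
    complete = vals.notna().all(axis=1)
    Y = vals.loc[complete].to_numpy(dtype=float)
    probe_ids = vals.index[complete]

    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    pinv = xtx_inv @ Xm.T  # p x n
    B = Y @ pinv.T  # probes x p
    resid = Y - B @ Xm.T
    df = n - p
    rss = (resid**2).sum(axis=1)
    s2 = rss / df

    nonzero = s2 > 1e-300
    if (~nonzero).any():
        logger.info("excluding %d probes with zero residual variance", int((~nonzero).sum()))

    gi = list(X.columns).index("group")
    if shrink_var:
        s2_prior = float(np.mean(s2[nonzero])) if nonzero.any() else 0.0
        s2_used = (prior_df * s2_prior + df * s2) / (prior_df + df)
        t_df = df + prior_df
    else:
        s2_used = s2
        t_df = df
    se = np.sqrt(s2_used * xtx_inv[gi, gi])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[:, gi] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), t_df)

    mean1 = Y[:, g == 1].mean(axis=1)
    mean0 = Y[:, g == 0].mean(axis=1)
    delta = mean1 - mean0

    out = pd.DataFrame(
        {
            "delta_beta": delta,
            "adjusted_delta_beta": B[:, gi],
            "mean_beta_ref": mean0,
            "mean_beta_alt": mean1,
            "t": t,
            "p": pvals,
        },
        index=probe_ids,
    )
    out = out[nonzero]
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = (out["q"] < fdr) & (out["delta_beta"].abs() >= delta_beta_min)
    if not m.coords.empty:
        out = out.join(m.coords[["chrom", "cpg_pos"]])
    out.attrs["group_levels"] = levels
    out.attrs["n_excluded_zero_variance"] = int((~nonzero).sum())
    out.attrs["n_samples"] = int(n)
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone along sorted p)."""
    q = multipletests(pvals, method="fdr_bh")[1]
    return q


def smooth_squared_stats(
    pos: np.ndarray, t2: np.ndarray, lambda_bp: float, scale_c: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel smoothing of squared statistics along one chromosome.

    Returns (smoothed statistic S_i, Satterthwaite p_i) where
    S_i = sum_j w_ij t2_j with w_ij = exp(-d_ij^2 / (2 sigma^2)),
    sigma = lambda_bp / scale_c, and the kernel truncated at lambda_bp.
    Under the null each t2_j is treated as chi-square(1), so
    S_i / c_i ~ chi-square(k_i) with c_i = sum w^2 / sum w and
    k_i = (sum w)^2 / sum w^2.
    """
    sigma = lambda_bp / scale_c
    order = np.argsort(pos, kind="stable")
    pos_s, t2_s = pos[order], t2[order]
    n = len(pos_s)
    S = np.empty(n)
    sw = np.empty(n)
    sw2 = np.empty(n)
    lo = np.searchsorted(pos_s, pos_s - lambda_bp, side="left")
    hi = np.searchsorted(pos_s, pos_s + lambda_bp, side="right")
    for i in range(n):
        d = pos_s[lo[i]:hi[i]] - pos_s[i]
        w = np.exp(-(d**2) / (2.0 * sigma**2))
        S[i] = float(w @ t2_s[lo[i]:hi[i]])
        sw[i] = w.sum()
        sw2[i] = float(w @ w)
    c = sw2 / sw
    k = sw**2 / sw2
    pv = stats.chi2.sf(S / c, k)
    # undo the sort
    S_out = np.empty(n)
    p_out = np.empty(n)
    S_out[order] = S
    p_out[order] = pv
    return S_out, p_out


def call_dmrs(
    dmps: pd.DataFrame,
    cfg: DMRConfig | None = None,
    null: str = "satterthwaite",
    perm_t: np.ndarray | None = None,
) -> list[DMRegion]:
    """Group smoothed-significant CpGs into differentially methylated regions.

    ``dmps`` must carry chrom, cpg_pos, t, p and delta_beta per probe (the
    output of :func:`fit_dmps` joined with coordinates).  With
    ``null='permutation'`` the smoothed statistic's per-CpG null is taken
    from ``perm_t`` (draws x probes array of t-statistics under permuted
    labels, aligned to ``dmps`` rows) instead of the chi-square
    approximation.
    """
    cfg = cfg or DMRConfig()
    required = {"chrom", "cpg_pos", "t", "p", "delta_beta"}
    missing = required - set(dmps.columns)
    if missing:
        raise ValueError(f"dmps frame lacks column(s) {sorted(missing)}")
    if null not in ("satterthwaite", "permutation"):
        raise ValueError(f"unknown null {null!r}")
    if null == "permutation" and perm_t is None:
        raise ValueError("null='permutation' requires perm_t")

    df = dmps.copy()
    if not df["cpg_pos"].is_monotonic_increasing:
        df = df.sort_values(["chrom", "cpg_pos"], kind="stable")
        logger.info("DMP input unsorted; sorted by (chrom, position)")
    smoothed_p = np.empty(len(df))
    smoothed_S = np.empty(len(df))
    row_of = pd.Series(np.arange(len(dmps)), index=dmps.index)
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = df.index.get_indexer(sub.index)
        pos = sub["cpg_pos"].to_numpy(dtype=float)
        t2 = sub["t"].to_numpy(dtype=float) ** 2
        S, pv = smooth_squared_stats(pos, t2, cfg.lambda_bp, cfg.scale_c)
        if null == "permutation":
            cols = row_of.loc[sub.index].to_numpy()
            null_S = np.empty((perm_t.shape[0], len(pos)))
            for b in range(perm_t.shape[0]):
                null_S[b], _ = smooth_squared_stats(
                    pos, perm_t[b, cols] ** 2, cfg.lambda_bp, cfg.scale_c
                )
            pv = (1.0 + (null_S >= S[None, :]).sum(axis=0)) / (perm_t.shape[0] + 1.0)
        smoothed_p[idx] = pv
        smoothed_S[idx] = S
    df["smoothed_stat"] = smoothed_S
    df["smoothed_p"] = smoothed_p
    df["smoothed_q"] = benjamini_hochberg(df["smoothed_p"].to_numpy())

    regions: list[DMRegion] = []
    sig = df[df["smoothed_q"] < cfg.fdr]
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("cpg_pos", kind="stable")
        pos = sub["cpg_pos"].to_numpy()
        breaks = np.where(np.diff(pos) > cfg.lambda_bp)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            block = sub.iloc[s:e]
            if len(block) < cfg.min_cpgs:
                continue
            mean_db = float(block["delta_beta"].mean())
            if abs(mean_db) < cfg.delta_beta_min:
                continue
            chi = -2.0 * np.log(np.clip(block["p"].to_numpy(), 1e-300, None)).sum()
            fisher_p = float(stats.chi2.sf(chi, 2 * len(block)))
            regions.append(
                DMRegion(
                    chrom=str(chrom),
                    start=int(block["cpg_pos"].min()),
                    end=int(block["cpg_pos"].max()) + 1,
                    n_cpgs=int(len(block)),
                    mean_delta_beta=mean_db,
                    min_smoothed_q=float(block["smoothed_q"].min()),
                    fisher_p=fisher_p,
                    probe_ids=tuple(block.index),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    logger.info("called %d DMRs from %d CpGs", len(regions), len(df))
    return regions


def variance_heterogeneity_test(
    m, probe_set, group: str, center: str = "median"
) -> pd.DataFrame:
    """Levene's test of equal variance between two groups, per probe.

    Returns per-probe statistic, p, BH q across the probe set, per-group
    standard deviations and which group is more variable.  Probes constant
    in both groups are flagged undefined and excluded from BH.
    """
    levels = sorted(m.covariates[group].dropna().unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"group {group!r} must be binary")
    s0 = m.covariates.index[m.covariates[group] == levels[0]]
    s1 = m.covariates.index[m.covariates[group] == levels[1]]
    if min(len(s0), len(s1)) < 3:
        raise ValueError("each group needs n >= 3 for the variance test")
    rows = []
    for pid in probe_set:
        x = m.values.loc[pid, s0].dropna().to_numpy(dtype=float)
        y = m.values.loc[pid, s1].dropna().to_numpy(dtype=float)
        sd0, sd1 = float(np.std(x, ddof=1)), float(np.std(y, ddof=1))
        undefined = sd0 == 0.0 and sd1 == 0.0
        if undefined:
            stat, pv = np.nan, np.nan
        else:
            stat, pv = stats.levene(x, y, center=center)
        rows.append({
            "probe_id": pid, "statistic": stat, "p": pv,
            f"sd_{levels[0]}": sd0, f"sd_{levels[1]}": sd1,
            "more_variable": levels[0] if sd0 > sd1 else levels[1],
            "undefined": undefined,
        })
    out = pd.DataFrame(rows).set_index("probe_id")
    ok = ~out["undefined"]
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
    return out


def dmrs_to_frame(regions: list[DMRegion]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom, "start": r.start, "end": r.end, "n_cpgs": r.n_cpgs,
            "mean_delta_beta": r.mean_delta_beta, "min_smoothed_q": r.min_smoothed_q,
            "fisher_p": r.fisher_p,
        }
        for r in regions
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs",
                                       "mean_delta_beta", "min_smoothed_q", "fisher_p"])


def dmrs_to_bed(regions: list[DMRegion], path) -> None:
    """Regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tDMR_{i+1}\t"
                     f"{r.mean_delta_beta:.4f}\t.\n")
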
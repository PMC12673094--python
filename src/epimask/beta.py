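"""Beta-value matrix container and operations.

A :class:`BetaMatrix` holds methylation fractions (probes x samples, values
in [0, 1], missing allowed) together with per-sample covariates and
per-probe coordinates.  Operations: cross-platform merge by coordinate,
replicate-pair correlation, variance-ranked PCA with covariate association,
per-context global methylation comparison, and Ward (ward.D2) hierarchical
clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

logger = logging.getLogger(__name__)


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions plus aligned metadata.

    ``values``: DataFrame indexed by probe id, columns = sample ids.
    ``covariates``: DataFrame indexed by sample id (same order not required,
    but the id sets must match); may include a ``platform`` column.
    ``coords``: DataFrame indexed by probe id with ``chrom`` and ``cpg_pos``.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    coords: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        finite = v[~np.isnan(v)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("beta values must lie in [0, 1] (or be missing)")
        if not self.covariates.empty:
            if set(self.covariates.index) != set(self.values.columns):
                raise ValueError("covariate table not aligned 1:1 with samples")
            self.covariates = self.covariates.loc[self.values.columns]
        if not self.coords.empty:
            missing = self.values.index.difference(self.coords.index)
            if len(missing):
                raise ValueError(f"coords missing for {len(missing)} probes")
            self.coords = self.coords.loc[self.values.index]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missingness(self) -> pd.Series:
        """Per-probe fraction of missing values."""
        return self.values.isna().mean(axis=1)

    def to_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.values.to_csv(f"{prefix}_beta.tsv", sep="\t")
        if not self.covariates.empty:
            self.covariates.to_csv(f"{prefix}_covariates.tsv", sep="\t")
        if not self.coords.empty:
            self.coords.to_csv(f"{prefix}_coords.tsv", sep="\t")

    @classmethod
    def from_tsv(cls, beta_path, covariates_path=None, coords_path=None) -> "BetaMatrix":
        values = pd.read_csv(beta_path, sep="\t", index_col=0)
        cov = pd.read_csv(covariates_path, sep="\t", index_col=0) if covariates_path else pd.DataFrame()
        coords = pd.read_csv(coords_path, sep="\t", index_col=0) if coords_path else pd.DataFrame()
        return cls(values=values, covariates=cov, coords=coords)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray
    loadings: pd.DataFrame  # probes x components
    n_positions: int


def merge_platform_matrices(a: BetaMatrix, b: BetaMatrix) -> BetaMatrix:
    """Merge two platforms on shared genomic coordinates.

    Probes are matched by (chrom, cpg_pos); samples are concatenated.  Both
    inputs must be replicate-collapsed and build-harmonised upstream.
    """
    if a.coords.empty or b.coords.empty:
        raise ValueError("both matrices need probe coordinates to merge")
    dup = set(a.values.columns) & set(b.values.columns)
    if dup:
        raise ValueError(f"duplicate sample ids across platforms: {sorted(dup)[:5]}")

    key_a = pd.MultiIndex.from_frame(a.coords[["chrom", "cpg_pos"]])
    key_b = pd.MultiIndex.from_frame(b.coords[["chrom", "cpg_pos"]])
    shared = key_a.intersection(key_b)
    if len(shared) == 0:
        raise ValueError("no probes shared by genomic coordinate; nothing to merge")

    ia = pd.Series(np.arange(len(key_a)), index=key_a)
    ib = pd.Series(np.arange(len(key_b)), index=key_b)
    rows_a = a.values.iloc[ia.loc[shared].to_numpy()]
    rows_b = b.values.iloc[ib.loc[shared].to_numpy()]
    rows_b.index = rows_a.index  # identify rows by the first platform's probe ids
    values = pd.concat([rows_a, rows_b], axis=1)

    cov_a = a.covariates.copy() if not a.covariates.empty else pd.DataFrame(index=a.values.columns)
    cov_b = b.covariates.copy() if not b.covariates.empty else pd.DataFrame(index=b.values.columns)
    if "platform" not in cov_a.columns:
        cov_a["platform"] = "a"
    if "platform" not in cov_b.columns:
        cov_b["platform"] = "b"
    covariates = pd.concat([cov_a, cov_b])

    coords = a.coords.loc[rows_a.index]
    logger.info("platform merge: %d shared sites, %d samples", len(shared), values.shape[1])
    return BetaMatrix(values=values, covariates=covariates, coords=coords)


def replicate_correlation(
    m: BetaMatrix, pairs: Sequence[tuple[str, str]], method: str = "spearman"
) -> pd.DataFrame:
    """Correlation between paired samples over pairwise-complete probes.

    Returns a frame with one row per pair (rho, n_probes) plus min/median
    summary attributes in ``.attrs``.  Constant vectors yield an explicit
    ``undefined`` flag rather than a silent NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be spearman or pearson, got {method!r}")
    rows = []
    for s1, s2 in pairs:
        for s in (s1, s2):
            if s not in m.values.columns:
                raise KeyError(f"sample {s!r} absent from matrix")
        x = m.values[s1].to_numpy(dtype=float)
        y = m.values[s2].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if x.size < 3:
            raise ValueError(f"pair ({s1}, {s2}) has fewer than 3 shared non-missing probes")
        undefined = np.ptp(x) == 0 or np.ptp(y) == 0
        if undefined:
            rho = np.nan
        elif method == "spearman":
            rho = stats.spearmanr(x, y).statistic
        else:
            rho = stats.pearsonr(x, y).statistic
        rows.append({"sample_1": s1, "sample_2": s2, "rho": rho,
                     "n_probes": int(x.size), "undefined": undefined})
    out = pd.DataFrame(rows)
    defined = out.loc[~out["undefined"], "rho"]
    out.attrs["min_rho"] = float(defined.min()) if len(defined) else np.nan
    out.attrs["median_rho"] = float(defined.median()) if len(defined) else np.nan
    return out


def pca_top_variable(m: BetaMatrix, k: int = 10000, impute: bool = False) -> PCAResult:
    """PCA of samples over the k most variable positions.

    Rows with missing values are dropped (or mean-imputed per row with
    ``impute=True``), rows ranked by variance, the top k retained, features
    centred (no unit-variance scaling) and decomposed by SVD.
    """
    if m.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    vals = m.values
    if impute:
        vals = vals.apply(lambda r: r.fillna(r.mean()), axis=1)
    else:
        vals = vals.dropna(axis=0, how="any")
    if vals.shape[0] == 0:
        raise ValueError("no complete probes available for PCA")
    if k > vals.shape[0]:
        logger.warning("k=%d exceeds available probes (%d); capping", k, vals.shape[0])
        k = vals.shape[0]
    variances = vals.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:k]
    top = vals.index[vals.index.isin(top)]  # restore genomic order for determinism
    X = vals.loc[top].to_numpy(dtype=float).T  # samples x probes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    var = (s**2) / (n - 1)
    total_var = Xc.var(axis=0, ddof=1).sum()
    frac = var / total_var if total_var > 0 else np.zeros_like(var)
    ncomp = len(s)
    scores = pd.DataFrame(
        U * s, index=m.values.columns, columns=[f"PC{i+1}" for i in range(ncomp)]
    )
    loadings = pd.DataFrame(Vt.T, index=top, columns=scores.columns)
    return PCAResult(scores=scores, variance_fraction=frac, loadings=loadings, n_positions=int(k))


def pc_covariate_association(
    p: PCAResult, covariates: pd.DataFrame, n_components: int = 5
) -> pd.DataFrame:
    """Associate each component with each covariate.

    Categorical covariates: one-way ANOVA F-test on the component scores.
    Continuous covariates: Pearson correlation t-test.  Covariates with a
    single level are skipped with a note.
    """
    cov = covariates.loc[p.scores.index]
    rows = []
    for comp in p.scores.columns[:n_components]:
        y = p.scores[comp].to_numpy(dtype=float)
        for name in cov.columns:
            c = cov[name]
            ok = c.notna().to_numpy()
            if ok.sum() < 3:
                continue
            if pd.api.types.is_numeric_dtype(c) and c.nunique() > 8:
                r, pval = stats.pearsonr(y[ok], c.to_numpy(dtype=float)[ok])
                stat, kind = r, "pearson_r"
            else:
                groups = [y[ok][(c[ok] == lev).to_numpy()] for lev in c[ok].unique()]
                groups = [g for g in groups if g.size > 0]
                if len(groups) < 2:
                    logger.info("covariate %s has a single level; skipped", name)
                    continue
                f, pval = stats.f_oneway(*groups)
                stat, kind = f, "anova_F"
            rows.append({"component": comp, "covariate": name,
                         "statistic": float(stat), "kind": kind, "p_value": float(pval)})
    return pd.DataFrame(rows)


def global_context_methylation(
    m: BetaMatrix,
    context_probes: Mapping[str, Sequence[str]],
    group: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample median beta per context and two-group Wilcoxon comparison.

    ``context_probes`` maps context name (CGI, shore, LINE-1, ...) to probe
    ids.  ``group`` names a two-level covariate column.  Returns
    (per-sample medians, per-context test results).  For group sizes <= 8
    per arm the rank-sum test is exact; otherwise normal approximation with
    tie correction.
    """
    levels = m.covariates[group].dropna().unique()
    if len(levels) != 2:
        raise ValueError(f"group {group!r} must have exactly 2 levels, got {list(levels)}")
    g0 = m.covariates.index[(m.covariates[group] == levels[0])]
    g1 = m.covariates.index[(m.covariates[group] == levels[1])]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("empty group")

    med_rows = {}
    for ctx, probe_ids in context_probes.items():
        probe_ids = [pid for pid in probe_ids if pid in m.values.index]
        if not probe_ids:
            raise ValueError(f"context {ctx!r} has no probes present in the matrix")
        med_rows[ctx] = m.values.loc[probe_ids].median(axis=0, skipna=True)
    medians = pd.DataFrame(med_rows)  # samples x contexts

    test_rows = []
    exact = min(len(g0), len(g1)) <= 8
    for ctx in medians.columns:
        x = medians.loc[g0, ctx].dropna().to_numpy()
        y = medians.loc[g1, ctx].dropna().to_numpy()
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
        test_rows.append({
            "context": ctx, "group_a": levels[0], "group_b": levels[1],
            "median_a": float(np.median(x)), "median_b": float(np.median(y)),
            "statistic": float(res.statistic), "p_value": float(res.pvalue),
        })
    return medians, pd.DataFrame(test_rows)


def cluster_samples(m: BetaMatrix, probe_set: Sequence[str]) -> dict:
    """Hierarchical clustering of samples on a probe set.

    Euclidean distance with Ward linkage on raw observations (scipy's
    ``ward`` on observation vectors is the ward.D2 variant: squared
    distances inside the update).  Returns the linkage matrix, leaf order
    and the re-ordered matrix slice.
    """
    probe_set = list(probe_set)
    if not probe_set:
        raise ValueError("probe_set is empty")
    sl = m.values.loc[probe_set]
    if sl.isna().any().any():
        raise ValueError("missing values in the clustering slice; drop or impute first")
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    X = sl.to_numpy(dtype=float).T  # samples x probes
    Z = linkage(X, method="ward", metric="euclidean")
    order = leaves_list(Z)
    ordered = sl.iloc[:, order]
    return {"linkage": Z, "leaf_order": [m.values.columns[i] for i in order],
            "ordered_matrix": ordered}
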
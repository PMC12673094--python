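"""Reference-based cell-type deconvolution and purity filtering.

Bulk methylation is modelled as a non-negative mixture of sorted-cell
reference profiles: for each sample, weights w solve

    min || R w - b ||^2   s.t.  w >= 0,  sum(w) <= 1

where R is the signature matrix (CpGs x cell types) and b the sample's
beta values at the signature CpGs.  The inequality constraint leaves room
for an implicit "other" compartment; an equality mode is available.  Tumour
purity is the weight of the designated tumour-lineage type, and the cohort
filter retains samples in the highest purity quartile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)


class RankDeficientReferenceError(ValueError):
    pass


@dataclass
class CellTypeReference:
    """Signature CpGs x cell types mean-beta matrix plus selection stats."""

    profiles: pd.DataFrame  # CpGs x types, values in [0, 1]
    selection_stat: pd.Series | None = None
    uninformative: bool = False

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("reference needs at least 2 cell types")
        v = self.profiles.to_numpy(dtype=float)
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValueError("reference beta values must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)


@dataclass
class ProportionEstimate:
    """Per-sample mixture weights, residual and purity."""

    sample_id: str
    weights: pd.Series  # per cell type, >= 0, sum <= 1
    residual_norm: float
    purity: float


def select_signature_cpgs(
    ref_profiles: pd.DataFrame, q: int
) -> CellTypeReference:
    """Pick the q most type-discriminating CpGs from candidate profiles.

    CpGs are ranked by the between-type one-way F statistic computed on the
    type means (with the spread of the means standing in for the group
    contrast, since profiles are means); selection is balanced between
    hyper- and hypo-extremes of the leading contrast (first type minus the
    mean of the rest): ``q // 2`` from the positive side, the remaining
    ``q - q // 2`` from the negative side.
    """
    if ref_profiles.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    if q > ref_profiles.shape[0]:
        logger.warning("q=%d exceeds available CpGs (%d); capping", q, ref_profiles.shape[0])
        q = ref_profiles.shape[0]
    X = ref_profiles.to_numpy(dtype=float)
    grand = X.mean(axis=1)
    between = ((X - grand[:, None]) ** 2).sum(axis=1)
    # residual spread proxy: within-row spread around per-type value is zero
    # for mean profiles, so rank on the between-type sum of squares directly
    stat = pd.Series(between, index=ref_profiles.index)
    uninformative = bool(np.allclose(between, 0.0))
    if uninformative:
        logger.warning("reference profiles are identical across types; selection uninformative")
    contrast = X[:, 0] - X[:, 1:].mean(axis=1)
    # balance hyper/hypo extremes within the top-2q pool so a direction with
    # no informative CpGs never displaces genuinely discriminating ones
    ranked = stat.sort_values(ascending=False, kind="stable")
    pool = ranked.index[: min(2 * q, len(ranked))]
    csign = pd.Series(contrast, index=ref_profiles.index)
    pos = [i for i in pool if csign[i] > 0]
    neg = [i for i in pool if csign[i] <= 0]
    n_pos = min(q // 2, len(pos))
    n_neg = min(q - n_pos, len(neg))
    chosen = pos[:n_pos] + neg[:n_neg]
    if len(chosen) < q:  # one side short: top up from the pool by statistic
        taken = set(chosen)
        chosen += [i for i in pool if i not in taken][: q - len(chosen)]
    chosen_idx = ref_profiles.index[ref_profiles.index.isin(chosen)]
    return CellTypeReference(
        profiles=ref_profiles.loc[chosen_idx],
        selection_stat=stat.loc[chosen_idx],
        uninformative=uninformative,
    )


def _solve_weights(R: np.ndarray, b: np.ndarray, sum_to_one: bool) -> np.ndarray:
    """Constrained least squares: w >= 0 and sum(w) <= 1 (or == 1)."""
    k = R.shape[1]
    w0 = np.full(k, 1.0 / (k + 1))

    def objective(w):
        r = R @ w - b
        return 0.5 * float(r @ r)

    def grad(w):
        return R.T @ (R @ w - b)

    ctype = "eq" if sum_to_one else "ineq"
    cons = [{"type": ctype, "fun": lambda w: 1.0 - w.sum(), "jac": lambda w: -np.ones(k)}]
    res = optimize.minimize(
        objective, w0, jac=grad, bounds=[(0.0, 1.0)] * k, constraints=cons,
        method="SLSQP", options={"maxiter": 500, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    if not sum_to_one and w.sum() > 1.0:
        w = w / w.sum()
    return w


def estimate_cell_proportions(
    betas: pd.DataFrame,
    ref: CellTypeReference,
    tumour_type: str = "T-luminal",
    sum_to_one: bool = False,
    min_shared: int = 10,
) -> list[ProportionEstimate]:
    """Estimate mixture weights for every sample of a beta matrix.

    ``betas`` is probes x samples.  At least ``min_shared`` signature CpGs
    must be present; samples missing all signature CpGs are an error.
    Purity is the weight of ``tumour_type`` (0 if that type is absent from
    the reference).
    """
    shared = ref.profiles.index.intersection(betas.index)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} signature CpGs shared with the matrix (need >= {min_shared})"
        )
    R_full = ref.profiles.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R_full) < R_full.shape[1]:
        corr = np.corrcoef(R_full.T)
        pairs = [
            (ref.cell_types[i], ref.cell_types[j])
            for i in range(len(corr)) for j in range(i + 1, len(corr))
            if abs(corr[i, j]) > 1 - 1e-9
        ]
        raise RankDeficientReferenceError(f"collinear reference types: {pairs}")

    out: list[ProportionEstimate] = []
    for sample in betas.columns:
        b = betas.loc[shared, sample].to_numpy(dtype=float)
        ok = ~np.isnan(b)
        if ok.sum() == 0:
            raise ValueError(f"sample {sample!r} has no non-missing signature CpGs")
        R, bb = R_full[ok], b[ok]
        w = _solve_weights(R, bb, sum_to_one=sum_to_one)
        weights = pd.Series(w, index=ref.cell_types)
        purity = float(weights.get(tumour_type, 0.0))
        out.append(
            ProportionEstimate(
                sample_id=sample,
                weights=weights,
                residual_norm=float(np.linalg.norm(R @ w - bb)),
                purity=purity,
            )
        )
    return out


def purity_quartile_filter(
    estimates: Sequence[ProportionEstimate],
    group: Mapping[str, object] | None = None,
    group_level: object | None = None,
) -> list[str]:
    """Retain samples with purity >= the group's 75th percentile.

    ``group``/``group_level`` optionally restrict the filter to one
    subgroup (e.g. tumour samples of one ancestry); other samples are not
    returned.  Percentile uses linear interpolation (numpy default);
    boundary ties are retained.  Groups smaller than 4 are refused.
    """
    if group is not None and group_level is not None:
        pool = [e for e in estimates if group.get(e.sample_id) == group_level]
    else:
        pool = list(estimates)
    if len(pool) < 4:
        raise ValueError(f"quartile filter needs >= 4 samples, got {len(pool)}")
    purities = np.array([e.purity for e in pool], dtype=float)
    threshold = float(np.percentile(purities, 75, method="linear"))
    return [e.sample_id for e in pool if e.purity >= threshold]


def estimates_to_frame(estimates: Sequence[ProportionEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        row = {"sample_id": e.sample_id, "residual_norm": e.residual_norm, "purity": e.purity}
        row.update({f"w_{t}": w for t, w in e.weights.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
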
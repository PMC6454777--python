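"""Z-score normalization, dataset pooling and differential testing.

The meta-analysis recipe: each molecular layer is Z-scored per gene within
each originating dataset (subtract the per-dataset mean, divide by the
per-dataset sample standard deviation), the normalized datasets are pooled
sample-wise over the shared features, and tumor vs normal is compared per
feature with a two-tailed pooled-variance (Student) t-test. Bonferroni
adjustment controls the family-wise error over the features tested in the
run; significance is adjusted p < alpha (default 0.05).

Differential methylation follows the same test but, matching common
practice for gene-level methylation screens, applies the uncorrected
p < alpha cut-off and splits significant genes into hyper- (tumor mean
higher) and hypomethylated (tumor mean lower) lists.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix
from .errors import AnalysisError, ParameterError, PoolingError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "mean_tumor",
    "mean_normal",
    "t_stat",
    "p_raw",
    "p_adj",
    "direction",
    "significant",
    "degenerate",
    "n_tumor",
    "n_normal",
]


def zscore_normalize(matrix: OmicsMatrix, grouping: str = "per_dataset") -> OmicsMatrix:
    """Z-score each feature within each grouping block.

    grouping ``"per_dataset"`` uses the sample ``dataset_id`` blocks;
    ``"global"`` treats all samples as one block. Zero-variance features map
    to an all-zero row within the block (logged); features with fewer than
    two non-missing values in some block are dropped entirely (warned).
    """
    if grouping not in ("per_dataset", "global"):
        raise ParameterError(f"unknown grouping {grouping!r}")
    values = matrix.values.to_numpy(dtype=float)
    out = np.full_like(values, np.nan)
    if grouping == "global":
        blocks = [np.ones(matrix.n_samples, dtype=bool)]
    else:
        ds = matrix.dataset_id.to_numpy()
        blocks = [ds == d for d in pd.unique(ds)]

    drop = np.zeros(matrix.n_features, dtype=bool)
    n_zero_var = 0
    for mask in blocks:
        block = values[:, mask]
        n_obs = np.sum(~np.isnan(block), axis=1)
        drop |= n_obs < 2
        mean = np.nanmean(np.where(n_obs[:, None] >= 1, block, np.nan), axis=1)
        sd = np.nanstd(block, axis=1, ddof=1)
        zero_var = (sd == 0) & (n_obs >= 2)
        n_zero_var += int(zero_var.sum())
        safe_sd = np.where(sd > 0, sd, 1.0)
        z = (block - mean[:, None]) / safe_sd[:, None]
        z[zero_var] = np.where(np.isnan(block[zero_var]), np.nan, 0.0)
        out[:, mask] = z
    if n_zero_var:
        logger.info("zscore_normalize: %d zero-variance feature/block pairs set to 0", n_zero_var)
    if drop.any():
        logger.warning(
            "zscore_normalize: dropping %d feature(s) with <2 values in a block", int(drop.sum())
        )
    keep = ~drop
    return OmicsMatrix(
        layer=matrix.layer,
        values=pd.DataFrame(out[keep], index=matrix.features[keep], columns=matrix.samples),
        condition=matrix.condition,
        dataset_id=matrix.dataset_id,
        patient_id=matrix.patient_id,
    )


def pool_datasets(matrices: list[OmicsMatrix]) -> OmicsMatrix:
    """Concatenate datasets sample-wise over the intersection of features."""
    if not matrices:
        raise ParameterError("pool_datasets needs at least one matrix")
    layers = {m.layer for m in matrices}
    if len(layers) > 1:
        raise PoolingError(f"cannot pool mixed layers {sorted(layers)}")
    common = matrices[0].features
    for m in matrices[1:]:
        common = common.intersection(m.features)
    if len(common) == 0:
        raise PoolingError("empty feature intersection across datasets")
    dropped = sum(m.n_features - len(common) for m in matrices)
    if dropped:
        logger.info("pool_datasets: %d feature rows dropped outside the intersection", dropped)
    common = common.sort_values()
    return OmicsMatrix(
        layer=matrices[0].layer,
        values=pd.concat([m.values.loc[common] for m in matrices], axis=1),
        condition=pd.concat([m.condition for m in matrices]),
        dataset_id=pd.concat([m.dataset_id for m in matrices]),
        patient_id=pd.concat([m.patient_id for m in matrices]),
    )


def differential_test(
    pooled: OmicsMatrix, correction: str = "bonferroni", alpha: float = 0.05
) -> pd.DataFrame:
    """Two-tailed two-sample Student t-test per feature, tumor vs normal.

    Returns a DataFrame indexed by feature with columns
    ``mean_tumor, mean_normal, t_stat, p_raw, p_adj, direction, significant,
    degenerate, n_tumor, n_normal``. ``p_adj = min(1, p_raw * m)`` with m the
    number of features tested (Bonferroni), or equal to ``p_raw`` when
    ``correction="none"``.
    """
    if correction not in ("bonferroni", "none"):
        raise ParameterError(f"unknown correction {correction!r}")
    if not (0 <= alpha <= 1):
        raise ParameterError(f"alpha {alpha} outside [0, 1]")
    tum = pooled.values.loc[:, pooled.tumor_samples()].to_numpy(dtype=float)
    nor = pooled.values.loc[:, pooled.normal_samples()].to_numpy(dtype=float)
    if tum.shape[1] < 2 or nor.shape[1] < 2:
        raise AnalysisError(
            f"need >=2 tumor and >=2 normal samples, got {tum.shape[1]}/{nor.shape[1]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_raw = stats.ttest_ind(tum, nor, axis=1, equal_var=True, nan_policy="omit")
    t_stat = np.asarray(t_stat, dtype=float)
    p_raw = np.asarray(p_raw, dtype=float)
    mean_t = np.nanmean(tum, axis=1)
    mean_n = np.nanmean(nor, axis=1)

    # Degenerate rows: both groups zero variance. Equal means → no evidence
    # (t=0, p=1); different means → infinitely strong separation (p=0).
    var_t = np.nanvar(tum, axis=1, ddof=1)
    var_n = np.nanvar(nor, axis=1, ddof=1)
    degenerate = (var_t == 0) & (var_n == 0)
    same = degenerate & np.isclose(mean_t, mean_n)
    diff = degenerate & ~np.isclose(mean_t, mean_n)
    t_stat[same], p_raw[same] = 0.0, 1.0
    t_stat[diff] = np.sign(mean_t[diff] - mean_n[diff]) * np.inf
    p_raw[diff] = 0.0

    m = len(p_raw)
    p_adj = np.minimum(1.0, p_raw * m) if correction == "bonferroni" else p_raw.copy()
    out = pd.DataFrame(
        {
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "t_stat": t_stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(mean_t > mean_n, "up", "down"),
            "significant": p_adj < alpha,
            "degenerate": degenerate,
            "n_tumor": np.sum(~np.isnan(tum), axis=1),
            "n_normal": np.sum(~np.isnan(nor), axis=1),
        },
        index=pooled.features,
    )
    out.index.name = "feature_id"
    return out


def select_top_k(results: pd.DataFrame, k: int, direction: str) -> list[str]:
    """The k significant features of ``direction`` with smallest adjusted p.

    Ties break by larger \\|t\\|, then lexicographic feature id. If fewer than
    k significant features exist, all are returned with a warning.
    """
    if k < 0:
        raise ParameterError(f"k must be >= 0, got {k}")
    if direction not in ("up", "down"):
        raise ParameterError(f"direction must be 'up' or 'down', got {direction!r}")
    pool = results[results["significant"] & (results["direction"] == direction)].copy()
    pool["abs_t"] = pool["t_stat"].abs()
    pool = pool.reset_index(names="feature_id")
    pool = pool.sort_values(by=["p_adj", "abs_t", "feature_id"], ascending=[True, False, True])
    ordered = [str(f) for f in pool["feature_id"]]
    if len(ordered) < k:
        logger.warning(
            "select_top_k: only %d significant %s-regulated features (k=%d)",
            len(ordered), direction, k,
        )
    return ordered[:k]


def differential_methylation(
    pooled_meth: OmicsMatrix, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Uncorrected p < alpha split into hyper- and hypomethylated gene lists."""
    res = differential_test(pooled_meth, correction="none", alpha=alpha)
    sig = res[res["significant"]]
    hyper = sorted(sig.index[sig["direction"] == "up"])
    hypo = sorted(sig.index[sig["direction"] == "down"])
    logger.info("differential_methylation: %d hyper, %d hypo at p<%g", len(hyper), len(hypo), alpha)
    return hyper, hypo
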
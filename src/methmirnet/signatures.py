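"""Per-patient gene-signature scores and clinical association statistics.

A gene signature (GS) score is the per-patient sum of the member features'
Z-scores. Composite signatures subtract an "adverse" component from a
"protective" one: mRNA-GS = TS-mRNA-GS - OG-mRNA-GS, miRNA-GS =
TS-miRNA-GS - OG-miRNA-GS. The methylation signature works on raw
methylation scores instead of Z-scores: meth-GS = sum over hypermethylated
members minus sum over hypomethylated members, so a high meth-GS means the
patient's tumor-suppressor genes are relatively more methylated than its
oncogenes.

Cumulative anabolic/catabolic enzyme scores summarize metabolic imbalance
per condition: for each enzyme role, the sum over enzymes of the enzyme's
mean Z-score within tumor and within normal samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix
from .errors import AlignmentError, AnalysisError, ParameterError, UndefinedResultError

logger = logging.getLogger(__name__)


@dataclass
class SignatureScore:
    """Per-sample signature score with member-coverage bookkeeping."""

    name: str
    layer: str
    scores: pd.Series       # index = sample ids
    n_members: int          # members requested
    n_members_used: int     # members present in the matrix

    def aligned_with(self, other: "SignatureScore") -> bool:
        return self.scores.index.equals(other.scores.index)


def gs_score(matrix: OmicsMatrix, members, name: str = "GS") -> SignatureScore:
    """Per-sample sum of member Z-scores (missing member rows dropped with a
    logged coverage count; missing cells ignored)."""
    members = sorted(set(members))
    if not members:
        raise UndefinedResultError(f"{name}: empty member set")
    present = [m for m in members if m in matrix.features]
    if not present:
        raise UndefinedResultError(f"{name}: no member present in the {matrix.layer} matrix")
    if len(present) < len(members):
        logger.info("%s: %d/%d members present in matrix", name, len(present), len(members))
    sub = matrix.values.loc[present]
    scores = sub.sum(axis=0, skipna=True)
    return SignatureScore(
        name=name,
        layer=matrix.layer,
        scores=scores,
        n_members=len(members),
        n_members_used=len(present),
    )


def composite_score(positive: SignatureScore, negative: SignatureScore,
                    name: str | None = None) -> SignatureScore:
    """positive - negative, per patient (exact antisymmetric difference)."""
    if not positive.aligned_with(negative):
        raise AlignmentError(
            f"composite_score: {positive.name} and {negative.name} cover different patients"
        )
    return SignatureScore(
        name=name or f"{positive.name}-minus-{negative.name}",
        layer=positive.layer,
        scores=positive.scores - negative.scores,
        n_members=positive.n_members + negative.n_members,
        n_members_used=positive.n_members_used + negative.n_members_used,
    )


def meth_gs_score(meth: OmicsMatrix, hyper_members, hypo_members,
                  name: str = "meth-GS") -> SignatureScore:
    """Raw-methylation composite: sum over hyper members minus sum over hypo
    members; high score = TS genes relatively more methylated."""
    hyper_present = [m for m in sorted(set(hyper_members)) if m in meth.features]
    hypo_present = [m for m in sorted(set(hypo_members)) if m in meth.features]
    if not hyper_present and not hypo_present:
        raise UndefinedResultError(f"{name}: no member present in the methylation matrix")
    zero = pd.Series(0.0, index=meth.samples)
    hyper_sum = meth.values.loc[hyper_present].sum(axis=0, skipna=True) if hyper_present else zero
    hypo_sum = meth.values.loc[hypo_present].sum(axis=0, skipna=True) if hypo_present else zero
    return SignatureScore(
        name=name,
        layer=meth.layer,
        scores=hyper_sum - hypo_sum,
        n_members=len(set(hyper_members)) + len(set(hypo_members)),
        n_members_used=len(hyper_present) + len(hypo_present),
    )


def catabolic_anabolic_scores(matrix: OmicsMatrix, enzyme_annotation: pd.DataFrame) -> pd.DataFrame:
    """Cumulative enzyme scores per role per condition.

    ``enzyme_annotation`` maps gene_id -> role in {anabolic, catabolic}.
    Returns a DataFrame indexed by role with columns tumor/normal, each cell
    the sum over annotated enzymes of the enzyme's mean Z-score within that
    condition.
    """
    for col in ("gene_id", "role"):
        if col not in enzyme_annotation.columns:
            raise AnalysisError(f"enzyme annotation missing column {col!r}")
    bad = set(enzyme_annotation["role"].unique()) - {"anabolic", "catabolic"}
    if bad:
        raise AnalysisError(f"unknown enzyme role(s) {sorted(bad)}")
    if enzyme_annotation["gene_id"].duplicated().any():
        dup = enzyme_annotation.loc[enzyme_annotation["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise AnalysisError(f"enzyme {dup!r} annotated more than once")
    tumor = matrix.tumor_samples()
    normal = matrix.normal_samples()
    out = {}
    for role in ("catabolic", "anabolic"):
        enzymes = enzyme_annotation.loc[enzyme_annotation["role"] == role, "gene_id"]
        present = [e for e in enzymes if e in matrix.features]
        if len(present) < len(enzymes):
            logger.info("%s: %d/%d enzymes present in matrix", role, len(present), len(enzymes))
        if present:
            sub = matrix.values.loc[present]
            out[role] = {
                "tumor": float(sub[tumor].mean(axis=1).sum()),
                "normal": float(sub[normal].mean(axis=1).sum()),
                "n_enzymes": len(present),
            }
        else:
            out[role] = {"tumor": 0.0, "normal": 0.0, "n_enzymes": 0}
    return pd.DataFrame(out).T[["tumor", "normal", "n_enzymes"]]


def correlate(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p over pairwise-complete observations."""
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    if len(x) != len(y):
        raise ParameterError("correlate: inputs must have equal length")
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        raise ParameterError("correlate needs >= 3 complete paired observations")
    xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise UndefinedResultError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


def compare_groups(score: SignatureScore, labels) -> tuple[float, float]:
    """Two-tailed Student t-test of a signature score across a two-level
    clinical factor (levels with < 2 patients raise ParameterError)."""
    labels = pd.Series(labels)
    common = score.scores.index.intersection(labels.index)
    labels = labels.loc[common].dropna()
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ParameterError(f"compare_groups needs exactly 2 levels, got {levels}")
    a = score.scores.loc[labels.index[labels == levels[0]]].dropna()
    b = score.scores.loc[labels.index[labels == levels[1]]].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs >= 2 patients")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
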
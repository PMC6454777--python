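"""Over-representation filtering and GSEA-style running-sum enrichment.

Candidate gene lists are annotated by a one-sided hypergeometric
over-representation test against user-supplied GMT gene sets; the
annotation filter keeps the union of members of the top-ranked terms
(default: top 10), intersected with the candidates.

The enrichment score (ES) is the classic weighted Kolmogorov-Smirnov
running sum over a ranked feature list: hits increment by |w|^p normalized
by the in-set total, misses decrement by 1/(N - |S|); ES is the signed
maximum deviation from zero. The nominal p-value comes from a phenotype
permutation null with +1 smoothing, one-tailed on the sign of the observed
ES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, OmicsMatrix
from .errors import ParameterError, UndefinedResultError

logger = logging.getLogger(__name__)


@dataclass
class EnrichedTerm:
    set_name: str
    overlap: int
    set_size: int
    universe_size: int
    candidate_size: int
    p: float


@dataclass
class GseaResult:
    set_name: str
    es: float
    nominal_p: float
    n_perm: int


def hypergeom_enrichment(
    candidates, gene_sets: GeneSetCollection, universe
) -> list[EnrichedTerm]:
    """One-sided hypergeometric tail p per gene set, ranked ascending by p
    (ties: larger overlap, then set name)."""
    candidates = set(candidates)
    universe = set(universe)
    if not candidates or not universe:
        raise ParameterError("candidates and universe must be non-empty")
    if not candidates <= universe:
        raise ParameterError("candidates must be a subset of the universe")
    m = len(universe)
    n_cand = len(candidates)
    terms = []
    for name, members in gene_sets.sets.items():
        in_universe = set(members) & universe
        k = len(in_universe & candidates)
        # P(X >= k) for X ~ Hypergeom(M=m, n=|set|, N=n_cand)
        p = float(stats.hypergeom.sf(k - 1, m, len(in_universe), n_cand))
        terms.append(
            EnrichedTerm(
                set_name=name,
                overlap=k,
                set_size=len(in_universe),
                universe_size=m,
                candidate_size=n_cand,
                p=min(1.0, p),
            )
        )
    terms.sort(key=lambda t: (t.p, -t.overlap, t.set_name))
    return terms


def annotation_filter(candidates, ranked_terms, gene_sets: GeneSetCollection,
                      top_n: int = 10) -> list[str]:
    """Union of the members of the ``top_n`` top-ranked terms, intersected
    with the candidates (sorted)."""
    if top_n <= 0:
        raise ParameterError(f"top_n must be >= 1, got {top_n}")
    keep: set[str] = set()
    for term in ranked_terms[:top_n]:
        keep |= set(gene_sets[term.set_name])
    return sorted(keep & set(candidates))


def terms_to_frame(terms: list[EnrichedTerm]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in terms])


# ---------------------------------------------------------------------------
# GSEA running sum
# ---------------------------------------------------------------------------

def gsea_es(ranked_features, weights, gene_set, weight_exponent: int = 1) -> float:
    """Signed maximum deviation of the running sum over a ranked list.

    ``ranked_features`` are ordered by the ranking metric (descending);
    ``weights`` are the metric values in the same order.
    """
    if weight_exponent not in (0, 1):
        raise ParameterError(f"weight_exponent must be 0 or 1, got {weight_exponent}")
    features = list(ranked_features)
    w = np.abs(np.asarray(weights, dtype=float)) ** weight_exponent
    in_set = np.array([f in gene_set for f in features], dtype=bool)
    n_hit = int(in_set.sum())
    n = len(features)
    if n_hit == 0:
        raise UndefinedResultError("gene set has no member in the ranked list")
    if n_hit == n:
        raise UndefinedResultError("gene set covers the entire ranked list")
    hit_total = w[in_set].sum()
    if hit_total == 0:
        # all in-set weights zero (exponent 1): fall back to equal increments
        increments = np.where(in_set, 1.0 / n_hit, 0.0)
    else:
        increments = np.where(in_set, w / hit_total, 0.0)
    decrement = 1.0 / (n - n_hit)
    steps = increments - np.where(in_set, 0.0, decrement)
    running = np.clip(np.cumsum(steps), -1.0, 1.0)  # clamp float round-off
    return float(running[np.argmax(np.abs(running))])


def _t_metric(values: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance t statistic per feature for class a vs b."""
    a = values[:, is_a]
    b = values[:, ~is_a]
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / denom
    return np.where(np.isfinite(t), t, 0.0)


def gsea_permutation_p(
    expr: OmicsMatrix,
    phenotype,
    gene_set,
    set_name: str = "",
    n_perm: int = 999,
    weight_exponent: int = 1,
    seed: int = 0,
) -> GseaResult:
    """Phenotype-permutation GSEA for one gene set.

    The ranking metric is the per-feature pooled-variance t statistic
    between the two phenotype classes. ``nominal_p = (1 + #{sign-matched
    permuted ES at least as extreme}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    phenotype = pd.Series(phenotype)
    levels = sorted(phenotype.dropna().unique())
    if len(levels) != 2:
        raise ParameterError(f"phenotype must have exactly 2 levels, got {levels}")
    samples = phenotype.index.intersection(expr.samples)
    phenotype = phenotype.loc[samples]
    is_a = (phenotype == levels[0]).to_numpy()
    if is_a.sum() < 2 or (~is_a).sum() < 2:
        raise ParameterError("each phenotype class needs >= 2 samples")
    values = expr.values.loc[:, samples].to_numpy(dtype=float)
    features = list(expr.features)
    in_set_mask = np.array([f in set(gene_set) for f in features], dtype=bool)
    if not in_set_mask.any():
        raise UndefinedResultError("gene set has no member in the expression matrix")

    def _es_from_labels(labels_a: np.ndarray) -> float:
        t = _t_metric(values, labels_a)
        order = np.argsort(-t, kind="stable")
        w = np.abs(t[order]) ** weight_exponent
        hits = in_set_mask[order]
        hit_total = w[hits].sum()
        n = len(features)
        n_hit = int(hits.sum())
        if hit_total == 0:
            inc = np.where(hits, 1.0 / n_hit, 0.0)
        else:
            inc = np.where(hits, w / hit_total, 0.0)
        steps = inc - np.where(hits, 0.0, 1.0 / (n - n_hit))
        running = np.clip(np.cumsum(steps), -1.0, 1.0)
        return float(running[np.argmax(np.abs(running))])

    es_obs = _es_from_labels(is_a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(is_a)
        es_p = _es_from_labels(perm)
        if es_obs >= 0 and es_p >= es_obs:
            count += 1
        elif es_obs < 0 and es_p <= es_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return GseaResult(set_name=set_name, es=es_obs, nominal_p=p, n_perm=n_perm)
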
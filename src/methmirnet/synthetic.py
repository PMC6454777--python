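"""Synthetic paired tumor/normal multi-omics cohorts with planted truth.

The generator emulates the statistical structure of a multi-dataset
tumor/normal meta-analysis cohort: unit-variance background features with
no group shift; planted tumor-suppressor (TS) genes shifted down and
oncogenes (OG) shifted up in tumors by ``effect_size`` standard deviations;
a per-patient latent aggressiveness factor A ~ N(0,1) that drives both
survival (proportional-hazards linear predictor ``hazard_log_ratio * A``)
and the planted features' prognostic value (planted genes load on A with
sign matching their role); planted miRNAs whose residual tracks the mean
residual of their target genes with a calibrated weight so each
(miRNA, target) pair correlates at ``-mirna_coupling`` within a condition;
and a methylation layer where coupled genes are shifted (hyper for TS,
hypo for OG) and anti-correlated with their own expression at magnitude
``meth_coupling``.

Everything downstream of the generator is testable against the emitted
:class:`CohortTruth` ledger.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from . import io as mio
from .containers import ClinicalTable, GeneSetCollection, InteractionTable, OmicsMatrix
from .errors import ConfigurationError, ParameterError


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the package's reference conditions: 120 tumors / 60 adjacent
    normals split round-robin into 4 pseudo-datasets, 2000 genes and 300
    miRNAs, 100 planted TS + 100 planted OG genes shifted by 1.5 SD, five
    planted hub miRNAs per role, couplings of 0.6, a per-unit log-hazard of
    log 2 on the latent aggressiveness factor, and 30% censoring.
    """

    n_tumor: int = 120
    n_normal: int = 60
    n_genes: int = 2000
    n_mirnas: int = 300
    n_planted_ts: int = 100
    n_planted_og: int = 100
    n_planted_ts_mirna: int = 5
    n_planted_og_mirna: int = 5
    effect_size: float = 1.5
    meth_coupling: float = 0.6
    mirna_coupling: float = 0.6
    hazard_log_ratio: float = math.log(2.0)
    censor_rate: float = 0.3
    n_datasets: int = 4
    seed: int = 0
    # secondary structure knobs
    targets_per_mirna: int = 20
    survival_loading: float = 0.85  # loading of planted genes on the A factor
    meth_fraction: float = 0.7      # fraction of planted genes meth-coupled
    n_background_meth: int = 50     # extra hyper/hypo genes outside planted sets
    n_decoy_edges: int = 400
    baseline_hazard: float = 0.1

    def validate(self) -> None:
        counts = {
            "n_tumor": self.n_tumor, "n_normal": self.n_normal,
            "n_genes": self.n_genes, "n_mirnas": self.n_mirnas,
            "n_planted_ts": self.n_planted_ts, "n_planted_og": self.n_planted_og,
            "n_planted_ts_mirna": self.n_planted_ts_mirna,
            "n_planted_og_mirna": self.n_planted_og_mirna,
            "n_datasets": self.n_datasets, "targets_per_mirna": self.targets_per_mirna,
            "n_background_meth": self.n_background_meth,
            "n_decoy_edges": self.n_decoy_edges,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.n_datasets < 1:
            raise ConfigurationError(f"n_datasets must be >= 1, got {self.n_datasets}")
        if self.n_planted_ts + self.n_planted_og > self.n_genes:
            raise ConfigurationError(
                f"n_planted_ts + n_planted_og = {self.n_planted_ts + self.n_planted_og} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if self.n_planted_ts_mirna + self.n_planted_og_mirna > self.n_mirnas:
            raise ConfigurationError("planted miRNA count exceeds n_mirnas")
        if not (0 <= self.censor_rate < 1):
            raise ConfigurationError(f"censor_rate must be in [0, 1), got {self.censor_rate}")
        for name in ("meth_coupling", "mirna_coupling", "meth_fraction", "survival_loading"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.baseline_hazard <= 0:
            raise ConfigurationError(f"baseline_hazard must be > 0, got {self.baseline_hazard}")
        if self.survival_loading ** 2 > 1:
            raise ConfigurationError("survival_loading^2 must be <= 1")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown cohort config key(s) {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CohortTruth:
    """Ledger of every planted structure in a synthetic cohort."""

    ts_genes: set[str] = field(default_factory=set)
    og_genes: set[str] = field(default_factory=set)
    ts_mirnas: set[str] = field(default_factory=set)
    og_mirnas: set[str] = field(default_factory=set)
    hyper_genes: set[str] = field(default_factory=set)
    hypo_genes: set[str] = field(default_factory=set)
    planted_edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ts_genes & self.og_genes:
            raise ConfigurationError("ts_genes and og_genes overlap")
        if self.ts_mirnas & self.og_mirnas:
            raise ConfigurationError("ts_mirnas and og_mirnas overlap")

    def is_empty(self) -> bool:
        return not (self.ts_genes or self.og_genes or self.ts_mirnas or self.og_mirnas)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for role, members in (
            ("ts_gene", self.ts_genes), ("og_gene", self.og_genes),
            ("ts_mirna", self.ts_mirnas), ("og_mirna", self.og_mirnas),
            ("hyper", self.hyper_genes), ("hypo", self.hypo_genes),
        ):
            rows.extend({"feature_id": f, "role": role} for f in sorted(members))
        return pd.DataFrame(rows, columns=["feature_id", "role"])

    @classmethod
    def from_frames(cls, roles: pd.DataFrame, edges: pd.DataFrame) -> "CohortTruth":
        by_role: dict[str, set[str]] = {}
        for _, row in roles.iterrows():
            by_role.setdefault(row["role"], set()).add(row["feature_id"])
        return cls(
            ts_genes=by_role.get("ts_gene", set()),
            og_genes=by_role.get("og_gene", set()),
            ts_mirnas=by_role.get("ts_mirna", set()),
            og_mirnas=by_role.get("og_mirna", set()),
            hyper_genes=by_role.get("hyper", set()),
            hypo_genes=by_role.get("hypo", set()),
            planted_edges=[
                (r["mirna_id"], r["gene_id"], float(r["confidence"]))
                for _, r in edges.iterrows()
            ],
        )


@dataclass
class SyntheticCohort:
    """All layers, clinical data, auxiliary tables and the truth ledger."""

    config: CohortConfig
    mrna: OmicsMatrix
    mirna: OmicsMatrix
    meth: OmicsMatrix
    clinical: ClinicalTable
    truth: CohortTruth
    interactions: InteractionTable
    enzyme_annotation: pd.DataFrame  # columns gene_id, role in {anabolic, catabolic}
    gene_sets: GeneSetCollection


def generate_survival_times(linear_predictor, baseline_hazard, censor_rate, seed):
    """Exponential proportional-hazards event times with independent
    exponential censoring calibrated to the requested censoring fraction.

    Subject i's event hazard is ``baseline_hazard * exp(linear_predictor_i)``.
    The censoring rate ``c`` solves ``mean_i[c / (c + h_i)] = censor_rate``
    (bisection), giving approximately the requested fraction of censored
    records. Returns (time, event) arrays; time > 0, event in {0, 1}.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if baseline_hazard <= 0:
        raise ParameterError(f"baseline_hazard must be > 0, got {baseline_hazard}")
    if not (0 <= censor_rate < 1):
        raise ParameterError(f"censor_rate must be in [0, 1), got {censor_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hazards = baseline_hazard * np.exp(lp)
    times = rng.exponential(1.0 / hazards)
    if censor_rate == 0:
        return times, np.ones_like(times, dtype=int)

    def censored_fraction(log_c):
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - censor_rate

    mid = math.log(baseline_hazard)
    log_c = optimize.brentq(censored_fraction, mid - 40, mid + 40)
    censor_times = rng.exponential(np.exp(-log_c), size=times.shape)
    event = (times <= censor_times).astype(int)
    observed = np.minimum(times, censor_times)
    return observed, event


def _sample_ids(config: CohortConfig):
    tumor = [f"T{i:04d}" for i in range(1, config.n_tumor + 1)]
    normal = [f"N{i:04d}" for i in range(1, config.n_normal + 1)]
    patients_t = [f"P{i:04d}" for i in range(1, config.n_tumor + 1)]
    # adjacent-normal samples reuse the first patients' ids (paired design)
    patients_n = [f"P{i:04d}" for i in range(1, config.n_normal + 1)]
    return tumor, normal, patients_t, patients_n


def _round_robin_datasets(n_samples: int, n_datasets: int) -> np.ndarray:
    return np.array([f"DS{1 + (i % n_datasets)}" for i in range(n_samples)])


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a fully-specified synthetic cohort; reproducible per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_s = config.n_tumor + config.n_normal
    is_tumor = np.concatenate(
        [np.ones(config.n_tumor, dtype=bool), np.zeros(config.n_normal, dtype=bool)]
    )
    tumor_ids, normal_ids, patients_t, patients_n = _sample_ids(config)
    samples = pd.Index(tumor_ids + normal_ids, name="sample_id")
    condition = pd.Series(np.where(is_tumor, "tumor", "normal"), index=samples)
    # tumor and normal samples interleave over pseudo-datasets independently
    dataset = pd.Series(
        np.concatenate([
            _round_robin_datasets(config.n_tumor, config.n_datasets),
            _round_robin_datasets(config.n_normal, config.n_datasets),
        ]),
        index=samples,
    )
    patient = pd.Series(patients_t + patients_n, index=samples, dtype="object")

    genes = np.array([f"GENE{i:05d}" for i in range(1, config.n_genes + 1)])
    mirnas = np.array([f"miR-{i:04d}" for i in range(1, config.n_mirnas + 1)])

    # ---- planted roles ----------------------------------------------------
    planted_genes = rng.choice(
        config.n_genes, size=config.n_planted_ts + config.n_planted_og, replace=False
    )
    ts_idx = planted_genes[: config.n_planted_ts]
    og_idx = planted_genes[config.n_planted_ts:]
    planted_mirs = rng.choice(
        config.n_mirnas,
        size=config.n_planted_ts_mirna + config.n_planted_og_mirna,
        replace=False,
    )
    tsm_idx = planted_mirs[: config.n_planted_ts_mirna]
    ogm_idx = planted_mirs[config.n_planted_ts_mirna:]

    # ---- latent aggressiveness factor and gene expression -----------------
    A = rng.standard_normal(n_s)
    w_a = config.survival_loading
    expr = rng.standard_normal((config.n_genes, n_s))
    sign = np.zeros(config.n_genes)
    sign[ts_idx] = -1.0
    sign[og_idx] = +1.0
    planted_mask = sign != 0
    resid = (
        w_a * sign[planted_mask, None] * A[None, :]
        + math.sqrt(max(0.0, 1 - w_a**2)) * expr[planted_mask]
    )
    expr[planted_mask] = (
        config.effect_size * sign[planted_mask, None] * is_tumor[None, :] + resid
    )

    # ---- planted miRNA hubs and their target sets -------------------------
    # Targets are assigned disjointly per role (round-robin over a
    # permutation) so each planted gene has at most one planted regulator.
    def _assign_targets(mir_indices, target_pool):
        pool = rng.permutation(target_pool)
        k = min(config.targets_per_mirna, len(pool)) if len(mir_indices) else 0
        assignment = {}
        cursor = 0
        for m in mir_indices:
            if len(pool) == 0 or k == 0:
                assignment[m] = np.array([], dtype=int)
                continue
            take = []
            for _ in range(k):
                take.append(pool[cursor % len(pool)])
                cursor += 1
            assignment[m] = np.array(take)
        return assignment

    ts_mir_targets = _assign_targets(tsm_idx, og_idx)   # TS miRNA -> OG genes
    og_mir_targets = _assign_targets(ogm_idx, ts_idx)   # OG miRNA -> TS genes

    mirna_vals = rng.standard_normal((config.n_mirnas, n_s))
    mir_sign = np.zeros(config.n_mirnas)
    mir_sign[tsm_idx] = -1.0
    mir_sign[ogm_idx] = +1.0
    planted_edges: list[tuple[str, str, float]] = []
    for m_idx, targets in {**ts_mir_targets, **og_mir_targets}.items():
        s_m = mir_sign[m_idx]
        if len(targets) == 0:
            mirna_vals[m_idx] = config.effect_size * s_m * is_tumor + mirna_vals[m_idx]
            continue
        k = len(targets)
        # residual of target genes around their condition means (unit variance)
        target_resid = expr[targets] - config.effect_size * sign[targets, None] * is_tumor[None, :]
        mean_resid = target_resid.mean(axis=0)
        sd_mean = math.sqrt(w_a**2 + (1 - w_a**2) / k)
        std_mean = mean_resid / sd_mean
        # calibrate the coupling so corr(miRNA, target | condition) = -mirna_coupling
        w_m = min(0.99, config.mirna_coupling / sd_mean)
        v = -w_m * std_mean + math.sqrt(1 - w_m**2) * mirna_vals[m_idx]
        mirna_vals[m_idx] = config.effect_size * s_m * is_tumor + v
        conf = rng.uniform(0.5, 1.0, size=k)
        for g_idx, c in zip(targets, conf):
            planted_edges.append((str(mirnas[m_idx]), str(genes[g_idx]), float(c)))

    # ---- methylation layer ------------------------------------------------
    meth = rng.standard_normal((config.n_genes, n_s))
    n_hyper_coupled = int(round(config.meth_fraction * len(ts_idx)))
    n_hypo_coupled = int(round(config.meth_fraction * len(og_idx)))
    hyper_coupled = rng.choice(ts_idx, size=n_hyper_coupled, replace=False) if n_hyper_coupled else np.array([], dtype=int)
    hypo_coupled = rng.choice(og_idx, size=n_hypo_coupled, replace=False) if n_hypo_coupled else np.array([], dtype=int)
    background = np.setdiff1d(np.arange(config.n_genes), planted_genes)
    n_bg = min(config.n_background_meth, len(background) // 2)
    bg_pick = rng.choice(background, size=2 * n_bg, replace=False) if n_bg else np.array([], dtype=int)
    hyper_bg, hypo_bg = bg_pick[:n_bg], bg_pick[n_bg:]

    rho = config.meth_coupling
    for idx_set, meth_sign in ((hyper_coupled, +1.0), (hypo_coupled, -1.0)):
        if len(idx_set) == 0:
            continue
        gene_resid = expr[idx_set] - config.effect_size * sign[idx_set, None] * is_tumor[None, :]
        meth[idx_set] = (
            meth_sign * config.effect_size * is_tumor[None, :]
            - rho * gene_resid
            + math.sqrt(1 - rho**2) * meth[idx_set]
        )
    for idx_set, meth_sign in ((hyper_bg, +1.0), (hypo_bg, -1.0)):
        if len(idx_set):
            meth[idx_set] += meth_sign * config.effect_size * is_tumor[None, :]

    # ---- decoy interactions ----------------------------------------------
    edge_keys = {(m, g) for m, g, _ in planted_edges}
    decoys = []
    attempts = 0
    while len(decoys) < config.n_decoy_edges and attempts < 20 * (config.n_decoy_edges + 1):
        attempts += 1
        m = str(mirnas[rng.integers(config.n_mirnas)])
        g = str(genes[rng.integers(config.n_genes)])
        if (m, g) in edge_keys:
            continue
        edge_keys.add((m, g))
        decoys.append((m, g, float(rng.uniform(0.0, 0.5))))
    inter = pd.DataFrame(
        planted_edges + decoys, columns=["mirna_id", "gene_id", "confidence"]
    )

    # ---- survival and clinical covariates ---------------------------------
    A_t = A[: config.n_tumor]
    lp = config.hazard_log_ratio * A_t
    os_time, os_event = generate_survival_times(
        lp, config.baseline_hazard, config.censor_rate, rng
    )
    rfs_time, rfs_event = generate_survival_times(
        lp, 1.5 * config.baseline_hazard, config.censor_rate, rng
    )

    def _grade_factor(levels, cuts, noise_sd=0.8):
        latent = A_t + rng.normal(0, noise_sd, size=config.n_tumor)
        qs = np.quantile(latent, cuts)
        out = np.full(config.n_tumor, levels[0], dtype=object)
        for lvl, q in zip(levels[1:], qs):
            out[latent > q] = lvl
        unknown = rng.random(config.n_tumor) < 0.05
        out[unknown] = "unknown"
        return out

    invasion = np.where(
        A_t + rng.normal(0, 0.8, size=config.n_tumor) > 0.5, "yes", "no"
    ).astype(object)
    invasion[rng.random(config.n_tumor) < 0.05] = "unknown"
    clinical_df = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event.astype(float),
            "rfs_time": rfs_time,
            "rfs_event": rfs_event.astype(float),
            "vascular_invasion": invasion,
            "stage": _grade_factor(("I", "II", "III"), (0.45, 0.8)),
            "grade": _grade_factor(("G1", "G2", "G3"), (0.4, 0.75)),
            "t_size": _grade_factor(("T1", "T2", "T3"), (0.45, 0.8)),
        },
        index=pd.Index(patients_t, name="patient_id"),
    )

    # ---- enzyme annotation (anabolic up / catabolic down, with exceptions) -
    # Proportions mirror a liver-cancer metabolic-imbalance profile: most
    # anabolic enzymes up-regulated, most catabolic enzymes down-regulated.
    f = min(1.0, len(ts_idx) / 76 if len(ts_idx) else 0, len(og_idx) / 33 if len(og_idx) else 0)
    n_anab_up, n_anab_down = int(31 * f), int(8 * f)
    n_catab_down, n_catab_up = int(68 * f), int(2 * f)
    og_perm = rng.permutation(og_idx)
    ts_perm = rng.permutation(ts_idx)
    enzyme_rows = []
    for g_idx in og_perm[:n_anab_up]:
        enzyme_rows.append({"gene_id": str(genes[g_idx]), "role": "anabolic"})
    for g_idx in ts_perm[:n_anab_down]:
        enzyme_rows.append({"gene_id": str(genes[g_idx]), "role": "anabolic"})
    for g_idx in ts_perm[n_anab_down:n_anab_down + n_catab_down]:
        enzyme_rows.append({"gene_id": str(genes[g_idx]), "role": "catabolic"})
    for g_idx in og_perm[n_anab_up:n_anab_up + n_catab_up]:
        enzyme_rows.append({"gene_id": str(genes[g_idx]), "role": "catabolic"})
    enzyme_annotation = pd.DataFrame(enzyme_rows, columns=["gene_id", "role"])

    # ---- synthetic gene sets (for enrichment / GSEA stages) ----------------
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    if len(ts_idx) and len(og_idx):
        n_mix = max(1, len(ts_idx) // 5)
        metab = [str(g) for g in genes[ts_perm[: int(0.8 * len(ts_idx))]]]
        metab += [str(g) for g in genes[rng.choice(background, size=n_mix, replace=False)]]
        cycle = [str(g) for g in genes[og_perm[: int(0.8 * len(og_idx))]]]
        cycle += [str(g) for g in genes[rng.choice(background, size=n_mix, replace=False)]]
        sets["METABOLIC_PROCESS_SYN"] = sorted(set(metab))
        desc["METABOLIC_PROCESS_SYN"] = "synthetic metabolic-pathway set enriched in planted TS genes"
        sets["CELL_CYCLE_SYN"] = sorted(set(cycle))
        desc["CELL_CYCLE_SYN"] = "synthetic cell-cycle set enriched in planted OG genes"
    n_random_sets = 20 if config.n_genes >= 2 else 0
    for i in range(1, n_random_sets + 1):
        size = min(int(rng.integers(20, 60)), max(1, config.n_genes // 2))
        members = sorted(str(g) for g in genes[rng.choice(config.n_genes, size=size, replace=False)])
        sets[f"RANDOM_SET_{i:02d}"] = members
        desc[f"RANDOM_SET_{i:02d}"] = "random background gene set"
    gene_sets = GeneSetCollection(sets=sets, descriptions=desc)

    truth = CohortTruth(
        ts_genes={str(genes[i]) for i in ts_idx},
        og_genes={str(genes[i]) for i in og_idx},
        ts_mirnas={str(mirnas[i]) for i in tsm_idx},
        og_mirnas={str(mirnas[i]) for i in ogm_idx},
        hyper_genes={str(genes[i]) for i in np.concatenate([hyper_coupled, hyper_bg])}
        if (len(hyper_coupled) + len(hyper_bg)) else set(),
        hypo_genes={str(genes[i]) for i in np.concatenate([hypo_coupled, hypo_bg])}
        if (len(hypo_coupled) + len(hypo_bg)) else set(),
        planted_edges=planted_edges,
    )

    def _layer(layer, values, features):
        return OmicsMatrix(
            layer=layer,
            values=pd.DataFrame(values, index=pd.Index(features, name="feature_id"),
                                columns=samples),
            condition=condition,
            dataset_id=dataset,
            patient_id=patient,
        )

    return SyntheticCohort(
        config=config,
        mrna=_layer("mRNA", expr, genes),
        mirna=_layer("miRNA", mirna_vals, mirnas),
        meth=_layer("methylation", meth, genes),
        clinical=ClinicalTable(data=clinical_df),
        truth=truth,
        interactions=InteractionTable(data=inter),
        enzyme_annotation=enzyme_annotation,
        gene_sets=gene_sets,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

COHORT_FILES = {
    "mrna": "mrna_matrix.tsv",
    "mrna_samples": "mrna_samples.tsv",
    "mirna": "mirna_matrix.tsv",
    "mirna_samples": "mirna_samples.tsv",
    "meth": "meth_matrix.tsv",
    "meth_samples": "meth_samples.tsv",
    "clinical": "clinical.tsv",
    "interactions": "interactions.tsv",
    "enzyme_annotation": "enzyme_annotation.tsv",
    "gene_sets": "gene_sets.gmt",
    "truth_roles": "truth_roles.tsv",
    "truth_edges": "truth_edges.tsv",
    "config": "cohort_config.json",
}


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write every cohort artifact as TSV/GMT/JSON; returns a file manifest
    with per-file row/column counts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    f = {k: directory / v for k, v in COHORT_FILES.items()}
    mio.write_expression_matrix(cohort.mrna, f["mrna"], f["mrna_samples"])
    mio.write_expression_matrix(cohort.mirna, f["mirna"], f["mirna_samples"])
    mio.write_expression_matrix(cohort.meth, f["meth"], f["meth_samples"])
    mio.write_clinical(cohort.clinical, f["clinical"])
    mio.write_interactions(cohort.interactions, f["interactions"])
    cohort.enzyme_annotation.to_csv(f["enzyme_annotation"], sep="\t", index=False,
                                    lineterminator="\n")
    mio.write_gmt(cohort.gene_sets, f["gene_sets"])
    cohort.truth.to_frame().to_csv(f["truth_roles"], sep="\t", index=False,
                                   lineterminator="\n")
    pd.DataFrame(cohort.truth.planted_edges,
                 columns=["mirna_id", "gene_id", "confidence"]).to_csv(
        f["truth_edges"], sep="\t", index=False, lineterminator="\n")
    with open(f["config"], "w", encoding="utf-8") as fh:
        json.dump(asdict(cohort.config), fh, indent=2)
        fh.write("\n")

    manifest = {}
    for key, path in f.items():
        entry = {"path": str(path)}
        if path.suffix == ".tsv":
            n_lines = sum(1 for _ in open(path, encoding="utf-8"))
            with open(path, encoding="utf-8") as fh:
                n_cols = len(fh.readline().rstrip("\n").split("\t"))
            entry.update(rows=n_lines - 1, columns=n_cols)
        manifest[key] = entry
    with open(directory / "cohort_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest


def read_cohort(directory) -> SyntheticCohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    f = {k: directory / v for k, v in COHORT_FILES.items()}
    if not f["config"].exists():
        from .errors import FormatError

        raise FormatError(f"not a cohort directory (missing {f['config'].name}): {directory}")
    with open(f["config"], encoding="utf-8") as fh:
        config = CohortConfig(**json.load(fh))
    roles = pd.read_csv(f["truth_roles"], sep="\t", dtype=str) if f["truth_roles"].exists() else pd.DataFrame(columns=["feature_id", "role"])
    edges = pd.read_csv(f["truth_edges"], sep="\t") if f["truth_edges"].exists() else pd.DataFrame(columns=["mirna_id", "gene_id", "confidence"])
    return SyntheticCohort(
        config=config,
        mrna=mio.read_expression_matrix(f["mrna"], f["mrna_samples"], layer="mRNA"),
        mirna=mio.read_expression_matrix(f["mirna"], f["mirna_samples"], layer="miRNA"),
        meth=mio.read_expression_matrix(f["meth"], f["meth_samples"], layer="methylation"),
        clinical=mio.read_clinical(f["clinical"]),
        truth=CohortTruth.from_frames(roles, edges),
        interactions=mio.read_interactions(f["interactions"]),
        enzyme_annotation=pd.read_csv(f["enzyme_annotation"], sep="\t", dtype=str),
        gene_sets=mio.read_gmt(f["gene_sets"]),
    )
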
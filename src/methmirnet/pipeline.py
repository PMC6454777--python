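"""End-to-end orchestration: normalize -> pool -> differential (three
layers) -> survival classification -> annotation filter -> inverse pairing
-> hub selection -> pruning -> methylation integration -> network export ->
signature scoring -> clinical associations -> GSEA.

Every stage writes its tabular output under the run directory; a manifest
records paths, sha256 checksums and per-stage counts so fixed-seed runs are
byte-reproducible and comparable. A stage failure aborts the run with the
stage name and leaves a FAILED marker next to the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, enrichment, io as mio, pairing, signatures
from .containers import OmicsMatrix
from .errors import AnalysisError, ConfigurationError, MethMirNetError, UndefinedResultError
from .network import build_network, integrate_methylation
from .survival import CandidateSet, classify_candidates, logrank_test, median_split
from .synthetic import CohortTruth, SyntheticCohort, read_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and sizes for one pipeline run; defaults are the
    reference settings (Bonferroni-adjusted p < 0.05 for expression layers,
    raw p < 0.05 for methylation and survival screens, top 1000 genes per
    direction, top 10 annotation terms, top 5 hub miRNAs, at most 2 edges
    per gene, nominal GSEA p from 999 phenotype permutations)."""

    input_dir: str = "."
    output_dir: str = "run"
    alpha_diff: float = 0.05
    alpha_meth: float = 0.05
    alpha_survival: float = 0.05
    alpha_gsea: float = 0.05
    top_k_genes: int = 1000
    top_n_terms: int = 10
    top_n_mirnas: int = 5
    max_edges_per_gene: int = 2
    min_confidence: float = 0.0
    n_perm: int = 999
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_diff", "alpha_meth", "alpha_survival", "alpha_gsea"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        for name in ("top_k_genes", "top_n_terms", "top_n_mirnas",
                     "max_edges_per_gene", "n_perm"):
            v = getattr(self, name)
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        if not (0 <= self.min_confidence <= 1):
            raise ConfigurationError(f"min_confidence must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown pipeline config key(s) {sorted(unknown)}")
        return cls(**raw)


class StageFailure(MethMirNetError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _normalize_and_pool(matrix: OmicsMatrix) -> OmicsMatrix:
    """Z-score each pseudo-dataset separately, then pool over shared features."""
    parts = [differential.zscore_normalize(m, "per_dataset") for m in matrix.split_by_dataset()]
    return differential.pool_datasets(parts)


class PipelineRun:
    """Holds in-memory results of one pipeline execution (see
    :func:`run_pipeline`); ``manifest`` maps stage -> outputs."""

    def __init__(self, config: PipelineConfig, cohort: SyntheticCohort):
        self.config = config
        self.cohort = cohort
        self.manifest: dict = {"stages": {}, "files": {}, "counts": {}}
        self.out = Path(config.output_dir)

    def _write(self, df: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = self.out / name
        df.to_csv(path, sep="\t", index=index, lineterminator="\n", na_rep="NA")
        self.manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}
        return path


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    """Execute the full analysis on a cohort directory; returns the run."""
    config.validate()
    cohort = read_cohort(config.input_dir)
    run = PipelineRun(config, cohort)
    run.out.mkdir(parents=True, exist_ok=True)
    counts = run.manifest["counts"]

    stage = "setup"
    try:
        # -- 1. normalize + pool + differential, per layer -------------------
        stage = "differential_mrna"
        mrna_z = _normalize_and_pool(cohort.mrna)
        diff_mrna = differential.differential_test(mrna_z, "bonferroni", config.alpha_diff)
        run._write(diff_mrna, "differential_mrna.tsv")
        top_up = differential.select_top_k(diff_mrna, config.top_k_genes, "up")
        top_down = differential.select_top_k(diff_mrna, config.top_k_genes, "down")
        counts["mrna_significant_up"] = len(top_up)
        counts["mrna_significant_down"] = len(top_down)
        run.mrna_z, run.diff_mrna = mrna_z, diff_mrna
        run.top_up, run.top_down = top_up, top_down

        stage = "differential_mirna"
        mirna_z = _normalize_and_pool(cohort.mirna)
        diff_mirna = differential.differential_test(mirna_z, "bonferroni", config.alpha_diff)
        run._write(diff_mirna, "differential_mirna.tsv")
        counts["mirna_significant"] = int(diff_mirna["significant"].sum())
        run.mirna_z, run.diff_mirna = mirna_z, diff_mirna

        stage = "differential_methylation"
        meth_pooled = differential.pool_datasets(cohort.meth.split_by_dataset())
        hyper, hypo = differential.differential_methylation(meth_pooled, config.alpha_meth)
        counts["hypermethylated"] = len(hyper)
        counts["hypomethylated"] = len(hypo)
        pd.DataFrame(
            [{"feature_id": g, "direction": "hyper"} for g in hyper]
            + [{"feature_id": g, "direction": "hypo"} for g in hypo]
        ).to_csv(run.out / "differential_methylation.tsv", sep="\t", index=False,
                 lineterminator="\n")
        run.manifest["files"]["differential_methylation.tsv"] = {
            "path": str(run.out / "differential_methylation.tsv"),
            "sha256": _sha256(run.out / "differential_methylation.tsv"),
        }
        run.hyper, run.hypo = hyper, hypo
        run.meth_pooled = meth_pooled

        # -- 2. survival classification --------------------------------------
        stage = "survival_classification_genes"
        ts_genes, og_genes = classify_candidates(
            diff_mrna, mrna_z, cohort.clinical, config.alpha_survival,
            features=top_up + top_down,
        )
        counts["ts_genes"] = len(ts_genes)
        counts["og_genes"] = len(og_genes)
        run._write(ts_genes.members, "candidates_ts_genes.tsv")
        run._write(og_genes.members, "candidates_og_genes.tsv")
        run.ts_genes, run.og_genes = ts_genes, og_genes

        stage = "survival_classification_mirnas"
        ts_mirnas, og_mirnas = classify_candidates(
            diff_mirna, mirna_z, cohort.clinical, config.alpha_survival
        )
        counts["ts_mirnas"] = len(ts_mirnas)
        counts["og_mirnas"] = len(og_mirnas)
        run._write(ts_mirnas.members, "candidates_ts_mirnas.tsv")
        run._write(og_mirnas.members, "candidates_og_mirnas.tsv")
        run.ts_mirnas, run.og_mirnas = ts_mirnas, og_mirnas

        # -- 3. annotation filter --------------------------------------------
        stage = "annotation_filter"
        universe = set(map(str, diff_mrna.index))
        filtered = {}
        for cand in (ts_genes, og_genes):
            ids = cand.feature_ids
            if ids:
                terms = enrichment.hypergeom_enrichment(ids, cohort.gene_sets, universe)
                kept = enrichment.annotation_filter(
                    ids, terms, cohort.gene_sets, config.top_n_terms
                )
                enrichment.terms_to_frame(terms).to_csv(
                    run.out / f"enrichment_{cand.role.lower()}_genes.tsv",
                    sep="\t", index=False, lineterminator="\n")
            else:
                kept = []
            filtered[cand.role] = kept
        counts["ts_genes_filtered"] = len(filtered["TS"])
        counts["og_genes_filtered"] = len(filtered["OG"])
        run.filtered = filtered

        def _subset(cand: CandidateSet, ids) -> CandidateSet:
            return CandidateSet(role=cand.role, layer=cand.layer,
                                members=cand.members.loc[list(ids)])

        ts_filtered = _subset(ts_genes, filtered["TS"])
        og_filtered = _subset(og_genes, filtered["OG"])

        # -- 4. pairing, hub selection, pruning ------------------------------
        stage = "mirna_pairing"
        networks = {}
        run.pairings = {}
        for mir_cand, gene_cand, role in (
            (og_mirnas, ts_filtered, "tumor_suppressor"),  # OG miRNAs -> TS genes
            (ts_mirnas, og_filtered, "oncogenic"),          # TS miRNAs -> OG genes
        ):
            pair = pairing.inverse_pairing(
                mir_cand, gene_cand, cohort.interactions, config.min_confidence
            )
            hubs = pairing.top_mirnas(pair, config.top_n_mirnas) if pair.targets else []
            pruned = pairing.prune_edges(pair, hubs, config.max_edges_per_gene)
            pairing.pairing_to_frame(pair, pruned).to_csv(
                run.out / f"pairing_{role}.tsv", sep="\t", index=False, lineterminator="\n")
            counts[f"{role}_hub_mirnas"] = len(hubs)
            counts[f"{role}_pruned_edges"] = len(pruned)
            networks[role] = (gene_cand, hubs, pruned)
            run.pairings[role] = pair

        # -- 5. methylation integration and network build --------------------
        stage = "network_build"
        flagged_ts, flagged_og = integrate_methylation(
            ts_genes.feature_ids, og_genes.feature_ids, hyper, hypo
        )
        counts["flagged_ts"] = len(flagged_ts)
        counts["flagged_og"] = len(flagged_og)
        run.flagged_ts, run.flagged_og = flagged_ts, flagged_og
        run.networks = {}
        for role, (gene_cand, hubs, pruned) in networks.items():
            flagged = flagged_ts if role == "tumor_suppressor" else flagged_og
            net = build_network(hubs, pruned, gene_cand.feature_ids, flagged, role)
            manifest = mio.write_network(net, run.out / "networks")
            run.manifest["stages"][f"network_{role}"] = manifest
            run.networks[role] = net
            counts[f"{role}_nodes"] = len(net.nodes)
            counts[f"{role}_edges"] = len(net.edges)

        # -- 6. signatures ----------------------------------------------------
        stage = "signatures"
        tumor_mrna = mrna_z.subset_samples(mrna_z.tumor_samples())
        tumor_mirna = mirna_z.subset_samples(mirna_z.tumor_samples())
        tumor_meth = cohort.meth.subset_samples(cohort.meth.tumor_samples())
        score_rows = {}
        run.scores = {}

        def _maybe(name, fn):
            try:
                s = fn()
            except UndefinedResultError as exc:
                logger.warning("signature %s undefined: %s", name, exc)
                return None
            run.scores[name] = s
            # key per patient for export
            pid = (tumor_mrna.patient_id if s.layer != "miRNA" else tumor_mirna.patient_id)
            score_rows[name] = pd.Series(s.scores.to_numpy(), index=pid.loc[s.scores.index])
            return s

        ts_gs = _maybe("TS-mRNA-GS", lambda: signatures.gs_score(
            tumor_mrna, filtered["TS"] or ts_genes.feature_ids, "TS-mRNA-GS"))
        og_gs = _maybe("OG-mRNA-GS", lambda: signatures.gs_score(
            tumor_mrna, filtered["OG"] or og_genes.feature_ids, "OG-mRNA-GS"))
        if ts_gs and og_gs:
            run.scores["mRNA-GS"] = signatures.composite_score(ts_gs, og_gs, "mRNA-GS")
            score_rows["mRNA-GS"] = pd.Series(
                run.scores["mRNA-GS"].scores.to_numpy(),
                index=tumor_mrna.patient_id.loc[run.scores["mRNA-GS"].scores.index])
        tsm_gs = _maybe("TS-miRNA-GS", lambda: signatures.gs_score(
            tumor_mirna, ts_mirnas.feature_ids, "TS-miRNA-GS"))
        ogm_gs = _maybe("OG-miRNA-GS", lambda: signatures.gs_score(
            tumor_mirna, og_mirnas.feature_ids, "OG-miRNA-GS"))
        if tsm_gs and ogm_gs:
            run.scores["miRNA-GS"] = signatures.composite_score(tsm_gs, ogm_gs, "miRNA-GS")
            score_rows["miRNA-GS"] = pd.Series(
                run.scores["miRNA-GS"].scores.to_numpy(),
                index=tumor_mirna.patient_id.loc[run.scores["miRNA-GS"].scores.index])
        if flagged_ts or flagged_og:
            _maybe("meth-GS", lambda: signatures.meth_gs_score(
                tumor_meth, flagged_ts, flagged_og, "meth-GS"))
            if "meth-GS" in run.scores:
                score_rows["meth-GS"] = pd.Series(
                    run.scores["meth-GS"].scores.to_numpy(),
                    index=tumor_meth.patient_id.loc[run.scores["meth-GS"].scores.index])
        if score_rows:
            score_df = pd.DataFrame(score_rows)
            score_df.index.name = "patient_id"
            run._write(score_df, "signature_scores.tsv")

        stage = "enzyme_scores"
        run.enzyme_scores = signatures.catabolic_anabolic_scores(
            mrna_z, cohort.enzyme_annotation
        )
        run._write(run.enzyme_scores, "enzyme_scores.tsv")

        # -- 7. clinical associations ----------------------------------------
        stage = "clinical_associations"
        assoc_rows = []
        clin = cohort.clinical.data
        for name, score in run.scores.items():
            if name not in ("mRNA-GS", "miRNA-GS", "meth-GS"):
                continue
            per_patient = score_rows[name].dropna()
            per_patient = per_patient[~per_patient.index.isna()]
            sig_obj = signatures.SignatureScore(
                name=name, layer=score.layer, scores=per_patient,
                n_members=score.n_members, n_members_used=score.n_members_used)
            for factor, a, b in (
                ("vascular_invasion", "no", "yes"),
                ("stage", "I", "III"),
                ("grade", "G1", "G3"),
                ("t_size", "T1", "T3"),
            ):
                lv = clin[factor]
                sel = lv[lv.isin([a, b])]
                try:
                    t, p = signatures.compare_groups(sig_obj, sel)
                except MethMirNetError:
                    continue
                assoc_rows.append({"signature": name, "factor": factor,
                                   "levels": f"{a}_vs_{b}", "t": t, "p": p})
            # survival stratification at the median
            for endpoint in ("os", "rfs"):
                surv = cohort.clinical.endpoint(endpoint)
                common = per_patient.index.intersection(surv.index)
                if len(common) < 4:
                    continue
                vals = per_patient.loc[common]
                labels = median_split(vals.to_numpy())
                hi = labels == "high"
                if hi.all() or (~hi).all():
                    continue
                tme = surv.loc[common, "time"].to_numpy()
                evt = surv.loc[common, "event"].to_numpy()
                chi, p = logrank_test(tme[hi], evt[hi], tme[~hi], evt[~hi])
                assoc_rows.append({"signature": name, "factor": f"{endpoint}_median_split",
                                   "levels": "high_vs_low", "t": chi, "p": p})
        run.associations = pd.DataFrame(
            assoc_rows, columns=["signature", "factor", "levels", "t", "p"])
        run._write(run.associations, "clinical_associations.tsv", index=False)

        # -- 8. GSEA -----------------------------------------------------------
        stage = "gsea"
        gsea_rows = []
        run.gsea = {}
        phenotype = mrna_z.condition
        for set_name in cohort.gene_sets.names():
            if not set_name.endswith("_SYN"):
                continue  # run on the structured sets; random sets are the null
            try:
                res = enrichment.gsea_permutation_p(
                    mrna_z, phenotype, cohort.gene_sets[set_name], set_name,
                    n_perm=config.n_perm, seed=config.seed,
                )
            except UndefinedResultError:
                continue
            run.gsea[set_name] = res
            gsea_rows.append({"set_name": set_name, "es": res.es,
                              "nominal_p": res.nominal_p, "n_perm": res.n_perm})
        pd.DataFrame(gsea_rows, columns=["set_name", "es", "nominal_p", "n_perm"]).to_csv(
            run.out / "gsea_results.tsv", sep="\t", index=False, lineterminator="\n")

        # -- 9. summary --------------------------------------------------------
        stage = "summary"
        run.manifest["config"] = asdict(config)
        with open(run.out / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(run.manifest, fh, indent=2, default=str)
            fh.write("\n")
    except Exception as exc:
        (run.out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n", encoding="utf-8")
        raise StageFailure(stage, exc) from exc
    return run


# ---------------------------------------------------------------------------
# Recovery metrics against the planted truth
# ---------------------------------------------------------------------------

def _sens_ppv(found: set, truth: set) -> dict:
    tp = len(found & truth)
    return {
        "n_found": len(found),
        "n_truth": len(truth),
        "tp": tp,
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "ppv": tp / len(found) if found else float("nan"),
    }


def recovery_report(run: PipelineRun, truth: CohortTruth | None = None) -> pd.DataFrame:
    """Sensitivity/PPV of every recovered set against the planted truth,
    plus hub-miRNA recovery and planted-edge retention through pruning."""
    truth = truth if truth is not None else run.cohort.truth
    if truth is None or truth.is_empty():
        raise AnalysisError("recovery_report requires a non-empty truth ledger")
    rows = {}
    rows["ts_genes"] = _sens_ppv(set(run.ts_genes.feature_ids), truth.ts_genes)
    rows["og_genes"] = _sens_ppv(set(run.og_genes.feature_ids), truth.og_genes)
    rows["ts_mirnas"] = _sens_ppv(set(run.ts_mirnas.feature_ids), truth.ts_mirnas)
    rows["og_mirnas"] = _sens_ppv(set(run.og_mirnas.feature_ids), truth.og_mirnas)
    rows["hyper"] = _sens_ppv(set(run.hyper), truth.hyper_genes)
    rows["hypo"] = _sens_ppv(set(run.hypo), truth.hypo_genes)
    rows["flagged_ts"] = _sens_ppv(set(run.flagged_ts), truth.ts_genes & truth.hyper_genes)
    rows["flagged_og"] = _sens_ppv(set(run.flagged_og), truth.og_genes & truth.hypo_genes)

    # hub recovery: selected miRNAs vs planted miRNAs of the matching role
    hub_truth = {"tumor_suppressor": truth.og_mirnas, "oncogenic": truth.ts_mirnas}
    for role, net in run.networks.items():
        rows[f"{role}_hubs"] = _sens_ppv(set(net.mirna_nodes()), hub_truth[role])

    # planted-edge retention through pruning, among edges whose miRNA was selected
    kept = {(m, g) for net in run.networks.values() for m, g, _ in net.edges}
    selected = {m for net in run.networks.values() for m in net.mirna_nodes()}
    candidate_genes = set(run.filtered["TS"]) | set(run.filtered["OG"])
    eligible = [
        (m, g) for m, g, _ in truth.planted_edges
        if m in selected and g in candidate_genes
    ]
    retained = sum((m, g) in kept for m, g in eligible)
    rows["planted_edges"] = {
        "n_found": len(kept), "n_truth": len(eligible), "tp": retained,
        "sensitivity": retained / len(eligible) if eligible else float("nan"),
        "ppv": retained / len(kept) if kept else float("nan"),
    }
    report = pd.DataFrame(rows).T
    report.index.name = "category"
    return report
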
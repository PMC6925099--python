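"""End-to-end benchmark stages wired together.

Each function here is one stage of the analysis — train/evaluate the RT
model, compare it against the naive similarity baseline, project predictions
onto an external method, annotate ions there — operating on the synthetic
benchmark. The numbered scripts under ``analysis/`` and the acceptance
script are thin drivers over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annotate as ann
from . import dlm as dlm_mod
from . import knn_baseline as knn
from . import projection as proj
from . import synthetic_data as synth
from .dlm import DEFAULT_NONRETAINED_CUTOFF, DlmConfig, ErrorSummary, RTModel
from .molecules import MoleculeRecord, fingerprint_matrix


@dataclass
class TrainedBenchmark:
    """A generated library with a trained model and validation-set errors."""

    records: list[MoleculeRecord]
    truth: synth.LibraryTruth
    train: list[MoleculeRecord]
    val: list[MoleculeRecord]
    model: RTModel
    pred_val: np.ndarray
    summary_all: ErrorSummary
    summary_retained: ErrorSummary

    @property
    def val_retained(self) -> list[MoleculeRecord]:
        return [r for r in self.val if r.rt >= DEFAULT_NONRETAINED_CUTOFF]

    @property
    def train_retained(self) -> list[MoleculeRecord]:
        return [r for r in self.train if r.rt >= DEFAULT_NONRETAINED_CUTOFF]


def train_benchmark(
    gen_config: synth.GeneratorConfig,
    dlm_config: DlmConfig | None = None,
    split_seed: int = 0,
) -> TrainedBenchmark:
    """Generate a library, split it, train the network, evaluate validation errors."""
    dlm_config = dlm_config or DlmConfig()
    records, truth = synth.gen_library(gen_config)
    train, val = dlm_mod.split_train_val(
        records, dlm_config.train_fraction, seed=split_seed
    )
    model = dlm_mod.train_dlm(train, dlm_config)
    pred_val = dlm_mod.predict_rt(model, val)
    exp_val = np.array([r.rt for r in val])
    ids_val = [r.mol_id for r in val]
    summary_all = dlm_mod.evaluate_errors(pred_val, exp_val, mol_ids=ids_val)
    summary_retained = dlm_mod.evaluate_errors(
        pred_val, exp_val, exclude_nonretained=True, mol_ids=ids_val
    )
    return TrainedBenchmark(
        records=records,
        truth=truth,
        train=train,
        val=val,
        model=model,
        pred_val=pred_val,
        summary_all=summary_all,
        summary_retained=summary_retained,
    )


@dataclass
class KnnComparison:
    """Per-threshold naive-vs-model error comparison on retained validation molecules."""

    naive_errors: np.ndarray
    dlm_errors: np.ndarray
    strata: dict[float, knn.SimilarityStratum]
    paired_reports: dict[float, knn.StatReport]
    subsample_reports: dict[float, knn.StatReport]


def compare_knn_vs_dlm(
    bench: TrainedBenchmark,
    k: int = 3,
    thresholds: tuple[float, ...] = knn.DEFAULT_THRESHOLDS,
    reps: int = 1000,
    seed: int = 0,
) -> KnnComparison:
    """Naive k-NN median-RT prediction vs the trained model, by similarity stratum.

    Non-retained molecules are excluded on both sides: their RT carries no
    structural signal, so neither predictor is meaningfully scored on them.
    Each stratum gets the paired location/scale tests; the subsampled
    Bonferroni procedure compares the two error samples as groups.
    """
    train_ret = bench.train_retained
    val_ret = bench.val_retained
    keep = np.array([r.rt >= DEFAULT_NONRETAINED_CUTOFF for r in bench.val])
    exp = np.array([r.rt for r in val_ret])
    naive_pred = knn.knn_median_rt(fingerprint_matrix(val_ret), train_ret, k=k)
    naive_err = 100.0 * np.abs(naive_pred - exp) / exp
    dlm_err = 100.0 * np.abs(bench.pred_val[keep] - exp) / exp
    strata = knn.stratify_by_similarity(
        val_ret, train_ret, thresholds, naive_errors=naive_err, dlm_errors=dlm_err
    )
    paired, grouped = {}, {}
    for t, stratum in strata.items():
        if stratum.n >= 2:
            paired[t] = knn.compare_paired_errors(stratum.naive_errors, stratum.dlm_errors)
            grouped[t] = knn.subsample_bonferroni_test(
                stratum.naive_errors, stratum.dlm_errors, reps=reps, seed=seed
            )
    return KnnComparison(
        naive_errors=naive_err,
        dlm_errors=dlm_err,
        strata=strata,
        paired_reports=paired,
        subsample_reports=grouped,
    )


@dataclass
class EcmProjection:
    """A fitted projection onto one external method and its held-out errors."""

    ecm: synth.EcmRealization
    fn: proj.ProjectionFn
    projected: pd.DataFrame  # mol_id, rt_projected_s, rt_ecm_s, is_anchor
    summary_heldout: ErrorSummary


def project_onto_ecm(
    bench: TrainedBenchmark,
    ecm: synth.EcmRealization,
    degree: int = 4,
    pred_ref: np.ndarray | None = None,
) -> EcmProjection:
    """Fit the anchor polynomial and project all predictions onto the method.

    ``pred_ref`` (reference-scale predictions for every library molecule, in
    library order) is computed from the trained model when not supplied. The
    error summary is over non-anchor molecules — the anchors were used to fit
    the map, so they do not score it.
    """
    if pred_ref is None:
        pred_ref = dlm_mod.predict_rt(bench.model, bench.records)
    pred_by_id = {r.mol_id: p for r, p in zip(bench.records, pred_ref)}
    table = ecm.table
    anchor_mask = table["mol_id"].isin(ecm.anchor_ids).to_numpy()
    anchors = proj.AnchorSet(
        ids=list(table["mol_id"][anchor_mask]),
        rt_pred=np.array([pred_by_id[m] for m in table["mol_id"][anchor_mask]]),
        rt_exp=table["rt_ecm_s"][anchor_mask].to_numpy(),
    )
    fn = proj.fit_projection(anchors, degree=degree, seed=ecm.config.seed)
    pred_all = np.array([pred_by_id[m] for m in table["mol_id"]])
    projected, _ = proj.project_rt(fn, pred_all)
    out = pd.DataFrame(
        {
            "mol_id": table["mol_id"],
            "rt_projected_s": projected,
            "rt_ecm_s": table["rt_ecm_s"],
            "is_anchor": anchor_mask,
        }
    )
    held = out[~anchor_mask]
    summary = proj.projection_error_summary(
        held["rt_projected_s"].to_numpy(),
        held["rt_ecm_s"].to_numpy(),
        mol_ids=list(held["mol_id"]),
    )
    return EcmProjection(ecm=ecm, fn=fn, projected=out, summary_heldout=summary)


@dataclass
class AnnotationResult:
    """Candidate search + ROC threshold + filtering + ranking on one method."""

    sets: list[ann.CandidateSet]
    roc: ann.RocResult
    threshold: float
    filter_report: ann.FilterReport
    ranking: ann.RankingReport


def annotate_on_ecm(
    bench: TrainedBenchmark,
    projection: EcmProjection,
    tol_ppm: float = 10.0,
    mass_noise_ppm: float = 0.5,
    n_queries: int | None = None,
    seed: int = 0,
) -> AnnotationResult:
    """Run the accurate-mass + RT-error annotation study on one external method.

    The searchable library is every molecule on the method, carrying its
    projected RT; queries are that method's ions with known identities.
    """
    rt_proj = dict(
        zip(projection.projected["mol_id"], projection.projected["rt_projected_s"])
    )
    by_id = {r.mol_id: r for r in bench.records}
    # a projection can stray below zero for aberrant predictions; floor it at
    # 1 s — such a candidate is hopeless regardless of the exact value
    library = [
        MoleculeRecord(
            mol_id=m, mono_mass=by_id[m].mono_mass, rt=max(float(rt_proj[m]), 1.0)
        )
        for m in projection.projected["mol_id"]
    ]
    queries = synth.gen_query_ions(
        projection.ecm,
        bench.records,
        mass_noise_ppm=mass_noise_ppm,
        n_queries=n_queries,
        seed=seed,
    )
    sets = ann.candidate_search(queries, library, tol_ppm=tol_ppm)
    roc = ann.roc_curve(sets)
    threshold = ann.select_threshold(roc)
    _, filter_report = ann.filter_candidates(sets, threshold)
    ranking = ann.ranking_report(sets)
    return AnnotationResult(
        sets=sets,
        roc=roc,
        threshold=threshold,
        filter_report=filter_report,
        ranking=ranking,
    )
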
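"""Naive similarity-based RT prediction and the statistical comparison machinery.

The naive predictor assumes similar molecules elute at similar times: a query
molecule's RT is the median RT of its k most Tanimoto-similar training
molecules (k = 3 by default). It serves as the control against which the
trained network is judged, stratified by how similar a validation molecule is
to its closest training neighbour (thresholds 95, 90, 80, 70 and 50%).

Two statistical procedures are provided:

* a paired comparison of two error vectors on the same molecules — Wilcoxon
  signed-rank for location and Ansari-Bradley for scale;
* an unequal-group comparison that repeatedly subsamples the larger group to
  the smaller group's size, runs a two-sample Wilcoxon rank test each time,
  Bonferroni-corrects by the number of repetitions and calls a significance
  level only when at least 95% of the corrected P values fall under it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .molecules import MoleculeRecord, fingerprint_matrix, tanimoto_matrix

DEFAULT_THRESHOLDS = (95.0, 90.0, 80.0, 70.0, 50.0)
SIGNIFICANCE_LEVELS = (0.0001, 0.001, 0.01, 0.05)  # most stringent first


@dataclass
class SimilarityStratum:
    """Validation molecules with >= 1 training neighbour above a threshold."""

    threshold: float
    member_ids: list[str]
    max_similarity: np.ndarray
    naive_errors: np.ndarray | None = None
    dlm_errors: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.member_ids)


@dataclass
class StatReport:
    """Outcome of one statistical comparison between two error samples."""

    test: str
    n: int
    p_location: float = float("nan")
    p_scale: float = float("nan")
    raw_p: np.ndarray | None = None
    corrected_p: np.ndarray | None = None
    significance: str = "ns"
    median_a: float = float("nan")
    median_b: float = float("nan")
    iqr_a: float = float("nan")
    iqr_b: float = float("nan")
    note: str = ""

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "n": self.n,
            "p_location": self.p_location,
            "p_scale": self.p_scale,
            "significance": self.significance,
            "median_a": self.median_a,
            "median_b": self.median_b,
            "iqr_a": self.iqr_a,
            "iqr_b": self.iqr_b,
            "note": self.note,
        }
        if self.raw_p is not None:
            d["raw_p"] = [float(p) for p in self.raw_p]
        if self.corrected_p is not None:
            d["corrected_p"] = [float(p) for p in self.corrected_p]
        return d


def iqr(x: np.ndarray) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles."""
    q1, q3 = np.percentile(np.asarray(x, dtype=np.float64), [25, 75])
    return float(q3 - q1)


def _significance_from_p(p: float) -> str:
    for level in SIGNIFICANCE_LEVELS:
        if p < level:
            return str(level)
    return "ns"


def knn_median_rt(
    query_fps: np.ndarray,
    training: list[MoleculeRecord],
    k: int = 3,
) -> np.ndarray:
    """Median RT of each query's k Tanimoto-nearest training molecules.

    Ties in similarity at the k-th neighbour are broken by ascending mol_id so
    repeated runs pick the same neighbour set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not training:
        raise ValueError("training set is empty")
    if k > len(training):
        raise ValueError(f"k={k} exceeds training size {len(training)}")
    train_fps = fingerprint_matrix(training)
    train_rt = np.asarray([r.rt for r in training], dtype=np.float64)
    train_ids = np.asarray([r.mol_id for r in training])
    sims = tanimoto_matrix(np.atleast_2d(query_fps), train_fps)
    out = np.empty(sims.shape[0])
    for i, row in enumerate(sims):
        # lexsort: primary key is the last column — descending similarity,
        # then ascending mol_id among equals
        order = np.lexsort((train_ids, -row))[:k]
        out[i] = np.median(train_rt[order])
    return out


def max_similarity_to_training(
    validation: list[MoleculeRecord], training: list[MoleculeRecord]
) -> np.ndarray:
    """For each validation molecule, its highest Tanimoto % to any training one."""
    sims = tanimoto_matrix(fingerprint_matrix(validation), fingerprint_matrix(training))
    return sims.max(axis=1)


def stratify_by_similarity(
    validation: list[MoleculeRecord],
    training: list[MoleculeRecord],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    naive_errors: np.ndarray | None = None,
    dlm_errors: np.ndarray | None = None,
) -> dict[float, SimilarityStratum]:
    """Group validation molecules by nearest-training-neighbour similarity.

    A molecule belongs to the stratum at threshold t when at least one
    training molecule is >= t% similar; strata are therefore nested from the
    strictest threshold down. Optional aligned error vectors are carried into
    each stratum for paired comparison.
    """
    if any(not 0 < t <= 100 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 100]")
    max_sim = max_similarity_to_training(validation, training)
    ids = np.asarray([r.mol_id for r in validation])
    strata: dict[float, SimilarityStratum] = {}
    for t in thresholds:
        mask = max_sim >= t
        strata[t] = SimilarityStratum(
            threshold=t,
            member_ids=list(ids[mask]),
            max_similarity=max_sim[mask],
            naive_errors=None if naive_errors is None else np.asarray(naive_errors)[mask],
            dlm_errors=None if dlm_errors is None else np.asarray(dlm_errors)[mask],
        )
    return strata


def compare_paired_errors(
    naive_errors: np.ndarray, dlm_errors: np.ndarray
) -> StatReport:
    """Paired location (Wilcoxon signed-rank) and scale (Ansari-Bradley) tests.

    The two vectors are errors of the two predictors on the same molecules.
    All-tied pairs leave the signed-rank statistic undefined; that case is
    flagged instead of raising.
    """
    a = np.asarray(naive_errors, dtype=np.float64)
    b = np.asarray(dlm_errors, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired error vectors must be aligned")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    note = ""
    if np.allclose(a, b):
        p_loc = float("nan")
        note = "all pairs tied; signed-rank statistic undefined"
    else:
        p_loc = float(stats.wilcoxon(a, b).pvalue)
    p_scale = float(stats.ansari(a, b).pvalue)
    return StatReport(
        test="paired wilcoxon signed-rank + ansari-bradley",
        n=len(a),
        p_location=p_loc,
        p_scale=p_scale,
        significance="ns" if np.isnan(p_loc) else _significance_from_p(p_loc),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=iqr(a),
        iqr_b=iqr(b),
        note=note,
    )


def subsample_bonferroni_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    reps: int = 1000,
    seed: int = 0,
) -> StatReport:
    """Size-matched repeated rank test with Bonferroni-corrected consensus.

    Each repetition draws a random subset of the larger group, of the smaller
    group's size, and runs a two-sample Wilcoxon rank (Mann-Whitney) test
    against the full smaller group. P values are multiplied by ``reps``
    (capped at 1) and the reported significance level is the most stringent
    of 0.05/0.01/0.001/0.0001 under which at least 95% of corrected P values
    fall, or ``ns``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    if len(a) >= len(b):
        larger, smaller, a_is_larger = a, b, True
    else:
        larger, smaller, a_is_larger = b, a, False
    m = len(smaller)
    raw = np.empty(reps)
    for r in range(reps):
        sub = larger[rng.choice(len(larger), size=m, replace=False)]
        x, y = (sub, smaller) if a_is_larger else (smaller, sub)
        raw[r] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    corrected = np.minimum(raw * reps, 1.0)
    significance = "ns"
    for level in reversed(SIGNIFICANCE_LEVELS):  # 0.05 up to 0.0001
        if (corrected < level).mean() >= 0.95:
            significance = str(level)
    return StatReport(
        test="subsampled two-sample wilcoxon rank, bonferroni-corrected",
        n=m,
        p_location=float(np.median(corrected)),
        raw_p=raw,
        corrected_p=corrected,
        significance=significance,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=iqr(a),
        iqr_b=iqr(b),
    )


def similarity_impact_analysis(
    validation: list[MoleculeRecord],
    training: list[MoleculeRecord],
    dlm_errors: np.ndarray,
    threshold: float = 90.0,
    reps: int = 1000,
    seed: int = 0,
) -> StatReport:
    """Does having a similar training molecule lower a molecule's RT error?

    Validation molecules are split into those with at least one training
    neighbour at >= ``threshold``% similarity and those with none, and the two
    error groups are compared with :func:`subsample_bonferroni_test`. An empty
    group is reported without running the test.
    """
    errors = np.asarray(dlm_errors, dtype=np.float64)
    if len(errors) != len(validation):
        raise ValueError("dlm_errors must align with the validation set")
    max_sim = max_similarity_to_training(validation, training)
    has = errors[max_sim >= threshold]
    lacks = errors[max_sim < threshold]
    if len(has) == 0 or len(lacks) == 0:
        return StatReport(
            test="similarity impact (subsampled wilcoxon)",
            n=0,
            note=f"empty group at threshold {threshold}% "
            f"(with-neighbour n={len(has)}, without n={len(lacks)}); no test run",
        )
    report = subsample_bonferroni_test(has, lacks, reps=reps, seed=seed)
    report.test = "similarity impact (subsampled wilcoxon)"
    return report
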
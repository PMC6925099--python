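"""Accurate-mass candidate search with RT-error ranking, ROC filtering and reports.

An annotated ion (an observed [M+H]+ or [M-H]- m/z with an experimental RT on
some chromatographic method) is searched against a compound library at a ppm
mass tolerance. Every mass-matched candidate gets a relative RT error — the
gap between the candidate's projected RT and the ion's experimental RT, as a
percentage of the experimental RT — and candidates are ranked by that error.

When the true identity of each ion is known, the error distributions of
correct and incorrect candidates define a ROC curve over an error-threshold
grid (0 to 100% in 2.5% steps): at threshold t, TP are correct identities
with error <= t, FN correct identities above t, FP incorrect candidates at or
under t and TN incorrect candidates above t. The operating threshold is the
one maximising Youden's J = TPR - FPR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molecules import MoleculeRecord, adduct_mz

DEFAULT_GRID = np.arange(0.0, 100.0 + 1e-9, 2.5)
DEFAULT_TOL_PPM = 10.0
CANDIDATE_COLUMNS = ["mol_id", "theo_mz", "ppm_error", "rt_projected_s", "rel_rt_error_pct"]


@dataclass
class QueryIon:
    """One annotated ion: observed m/z, adduct, and its experimental RT."""

    query_id: str
    mz: float
    adduct: str
    rt_exp: float
    true_mol_id: str | None = None


@dataclass
class CandidateSet:
    """Mass-matched candidates for one query ion, with their RT errors."""

    query: QueryIon
    candidates: pd.DataFrame

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def truth_present(self) -> bool:
        return (
            self.query.true_mol_id is not None
            and self.query.true_mol_id in set(self.candidates["mol_id"])
        )


@dataclass
class RocResult:
    """Confusion counts, rates and AUC over the error-threshold grid."""

    table: pd.DataFrame  # threshold, TP, TN, FP, FN, TPR, FPR
    auc: float
    n_correct: int
    n_incorrect: int
    n_truth_missing: int


@dataclass
class FilterReport:
    """Bookkeeping of RT-error filtering at a fixed threshold."""

    threshold: float
    n_before: int
    n_after: int
    per_query: pd.DataFrame  # query_id, before, after, truth_present, truth_lost
    n_truth_present: int
    n_truth_lost: int

    @property
    def truth_lost_fraction(self) -> float:
        """Fraction of correct identities filtered out (among sets with truth)."""
        if self.n_truth_present == 0:
            return float("nan")
        return self.n_truth_lost / self.n_truth_present


@dataclass
class RankingReport:
    """Percent of cases with the truth at exactly rank r, among cases with > m candidates.

    ``matrix`` is indexed by rank r in {1,2,3} with one column per candidate
    condition m in {>1,>2,>3}; cells with an empty denominator are NaN.
    ``top3_pct`` is the share of cases with more than three candidates whose
    truth ranks in the top three.
    """

    matrix: pd.DataFrame
    top3_pct: float
    n_cases: dict[int, int] = field(default_factory=dict)


def candidate_search(
    queries: list[QueryIon],
    library: list[MoleculeRecord],
    tol_ppm: float = DEFAULT_TOL_PPM,
    adducts: tuple[str, ...] = ("M+H", "M-H"),
) -> list[CandidateSet]:
    """ppm accurate-mass search of each query ion against the library.

    Library records need ``mono_mass``; their ``rt`` field is read as the RT
    already projected onto the query's chromatographic method (candidates
    without it get NaN RT errors). A query's own adduct decides which
    theoretical ion m/z each library mass is compared against; empty candidate
    sets are legitimate results.
    """
    if not library:
        raise ValueError("empty library")
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    masses = np.asarray([r.mono_mass for r in library], dtype=np.float64)
    if np.isnan(masses).any():
        raise ValueError("all library records need mono_mass")
    lib_ids = np.asarray([r.mol_id for r in library])
    lib_rt = np.asarray(
        [r.rt if r.rt is not None else np.nan for r in library], dtype=np.float64
    )
    theo_by_adduct = {a: np.array([adduct_mz(m, a) for m in masses]) for a in adducts}
    out = []
    for q in queries:
        if q.adduct not in theo_by_adduct:
            raise ValueError(f"query {q.query_id}: adduct {q.adduct!r} not in {adducts}")
        theo = theo_by_adduct[q.adduct]
        ppm = 1e6 * np.abs(q.mz - theo) / theo
        hit = ppm <= tol_ppm
        rel = 100.0 * np.abs(lib_rt[hit] - q.rt_exp) / q.rt_exp
        df = pd.DataFrame(
            {
                "mol_id": lib_ids[hit],
                "theo_mz": theo[hit],
                "ppm_error": ppm[hit],
                "rt_projected_s": lib_rt[hit],
                "rel_rt_error_pct": rel,
            }
        )
        out.append(CandidateSet(query=q, candidates=df))
    return out


def rank_candidates(cs: CandidateSet) -> tuple[pd.DataFrame, int | None]:
    """Candidates ordered by ascending RT error; rank of the truth if known.

    Equal errors are broken by ascending mol_id, so the order is stable.
    Returns (ordered table with a 1-based ``rank`` column, rank of the true
    identity or None when unknown/absent).
    """
    ordered = cs.candidates.sort_values(
        ["rel_rt_error_pct", "mol_id"], kind="mergesort"
    ).reset_index(drop=True)
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    rank_of_truth = None
    if cs.query.true_mol_id is not None:
        hit = ordered.index[ordered["mol_id"] == cs.query.true_mol_id]
        if len(hit):
            rank_of_truth = int(ordered.loc[hit[0], "rank"])
    return ordered, rank_of_truth


def _split_errors(sets: list[CandidateSet]) -> tuple[np.ndarray, np.ndarray, int]:
    correct, incorrect, missing = [], [], 0
    for cs in sets:
        if cs.query.true_mol_id is None:
            raise ValueError(f"query {cs.query.query_id} has no known truth")
        is_truth = cs.candidates["mol_id"] == cs.query.true_mol_id
        if cs.query.true_mol_id not in set(cs.candidates["mol_id"]):
            missing += 1
        correct.extend(cs.candidates.loc[is_truth, "rel_rt_error_pct"])
        incorrect.extend(cs.candidates.loc[~is_truth, "rel_rt_error_pct"])
    return np.asarray(correct), np.asarray(incorrect), missing


def roc_curve(
    sets: list[CandidateSet], grid: np.ndarray = DEFAULT_GRID
) -> RocResult:
    """ROC over the RT-error threshold grid, pooled across all candidate sets.

    Errors exactly at a threshold count as under it. The AUC is the trapezoid
    over the (FPR, TPR) path anchored at (0,0) and (1,1) — the curve's limits
    at thresholds below 0 and above every observed error.
    """
    correct, incorrect, missing = _split_errors(sets)
    if len(correct) == 0:
        raise ValueError("no correct identities among candidates; TPR undefined")
    if len(incorrect) == 0:
        raise ValueError("no incorrect candidates; FPR undefined")
    grid = np.asarray(grid, dtype=np.float64)
    tp = (correct[None, :] <= grid[:, None]).sum(axis=1)
    fp = (incorrect[None, :] <= grid[:, None]).sum(axis=1)
    fn = len(correct) - tp
    tn = len(incorrect) - fp
    tpr = tp / len(correct)
    fpr = fp / len(incorrect)
    table = pd.DataFrame(
        {"threshold": grid, "TP": tp, "TN": tn, "FP": fp, "FN": fn, "TPR": tpr, "FPR": fpr}
    )
    xs = np.concatenate(([0.0], fpr, [1.0]))
    ys = np.concatenate(([0.0], tpr, [1.0]))
    auc = float(np.trapezoid(ys, xs))
    return RocResult(
        table=table,
        auc=auc,
        n_correct=len(correct),
        n_incorrect=len(incorrect),
        n_truth_missing=missing,
    )


def select_threshold(roc: RocResult) -> float:
    """Threshold maximising Youden's J = TPR - FPR; ties go to the smallest."""
    j = roc.table["TPR"] - roc.table["FPR"]
    best = int(np.argmax(j.to_numpy()))  # argmax returns the first maximum
    return float(roc.table["threshold"].iloc[best])


def filter_candidates(
    sets: list[CandidateSet], threshold: float
) -> tuple[list[CandidateSet], FilterReport]:
    """Drop candidates whose RT error exceeds the threshold; account for losses.

    Returns the filtered sets plus a report of per-query and aggregate counts,
    including how many true identities the filter itself discarded.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept_sets, rows = [], []
    n_truth_present = n_truth_lost = 0
    for cs in sets:
        keep = cs.candidates["rel_rt_error_pct"] <= threshold
        kept = cs.candidates.loc[keep].reset_index(drop=True)
        kept_sets.append(CandidateSet(query=cs.query, candidates=kept))
        truth_present = cs.truth_present
        truth_lost = bool(
            truth_present and cs.query.true_mol_id not in set(kept["mol_id"])
        )
        n_truth_present += int(truth_present)
        n_truth_lost += int(truth_lost)
        rows.append(
            {
                "query_id": cs.query.query_id,
                "before": len(cs.candidates),
                "after": len(kept),
                "truth_present": truth_present,
                "truth_lost": truth_lost,
            }
        )
    per_query = pd.DataFrame(rows)
    report = FilterReport(
        threshold=threshold,
        n_before=int(per_query["before"].sum()) if len(per_query) else 0,
        n_after=int(per_query["after"].sum()) if len(per_query) else 0,
        per_query=per_query,
        n_truth_present=n_truth_present,
        n_truth_lost=n_truth_lost,
    )
    return kept_sets, report


def ranking_report(sets: list[CandidateSet]) -> RankingReport:
    """How often the true identity ranks first, second or third.

    Cell (r, >m) is the percentage of cases with more than m candidates whose
    truth sits at exactly rank r; the top-3 summary is the percentage of cases
    with more than three candidates whose truth ranks in the top three.
    Conditions with no qualifying cases give NaN cells.
    """
    records = []
    for cs in sets:
        _, rank = rank_candidates(cs)
        records.append((cs.n_candidates, rank))
    matrix = pd.DataFrame(
        index=pd.Index([1, 2, 3], name="rank"),
        columns=pd.Index([">1", ">2", ">3"], name="candidates"),
        dtype=float,
    )
    n_cases = {}
    for m in (1, 2, 3):
        qualifying = [(n, r) for n, r in records if n > m]
        n_cases[m] = len(qualifying)
        for r in (1, 2, 3):
            if qualifying:
                matrix.loc[r, f">{m}"] = (
                    100.0 * sum(rank == r for _, rank in qualifying) / len(qualifying)
                )
    top3 = [(n, r) for n, r in records if n > 3]
    top3_pct = (
        100.0 * sum(r is not None and r <= 3 for _, r in top3) / len(top3)
        if top3
        else float("nan")
    )
    return RankingReport(matrix=matrix, top3_pct=top3_pct, n_cases=n_cases)


def read_query_csv(path: str) -> list[QueryIon]:
    """Query ion CSV: query_id, mz, adduct, rt_experimental_s[, true_mol_id]."""
    df = pd.read_csv(path)
    return [
        QueryIon(
            query_id=str(row.query_id),
            mz=float(row.mz),
            adduct=str(row.adduct),
            rt_exp=float(row.rt_experimental_s),
            true_mol_id=str(row.true_mol_id)
            if "true_mol_id" in df.columns and pd.notna(row.true_mol_id)
            else None,
        )
        for row in df.itertuples(index=False)
    ]


def write_query_csv(queries: list[QueryIon], path: str) -> None:
    pd.DataFrame(
        {
            "query_id": [q.query_id for q in queries],
            "mz": [q.mz for q in queries],
            "adduct": [q.adduct for q in queries],
            "rt_experimental_s": [q.rt_exp for q in queries],
            "true_mol_id": [q.true_mol_id for q in queries],
        }
    ).to_csv(path, index=False)
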
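"""Deep regression of retention time from binary fingerprints.

The model is a fully connected feed-forward network in the typical scalar
regression configuration: four hidden relu layers of 1000, 500, 200 and 100
units feeding a single linear output unit, trained with Adam (learning rate
0.01), L2 weight penalty 1e-4 and mean-squared-error loss for a fixed 20
epochs at batch size 35. Binary fingerprint inputs are used unscaled and the
RT target is regressed in raw seconds.

Error evaluation reports relative (% of experimental RT) and absolute
(seconds) errors, with optional exclusion of non-retained molecules —
compounds eluting before the gradient start, whose RT carries no structural
signal and which inflate the mean far above the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .molecules import MoleculeRecord, fingerprint_matrix

#: Default retained/non-retained RT boundary in seconds. The gradient holds
#: initial conditions for the first minutes of the run, so non-retained
#: compounds elute well below this and a clear RT gap separates the groups.
DEFAULT_NONRETAINED_CUTOFF = 300.0


@dataclass
class DlmConfig:
    """Hyper-parameters of the retention-time regression network."""

    hidden_units: tuple[int, ...] = (1000, 500, 200, 100)
    l2_lambda: float = 0.0001
    learning_rate: float = 0.01
    epochs: int = 20
    batch_size: int = 35
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_units or any(h <= 0 for h in self.hidden_units):
            raise ValueError("hidden_units must be positive")
        for name in ("l2_lambda", "learning_rate", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class RTModel:
    """A trained RT regressor plus the configuration that produced it."""

    estimator: object
    config: DlmConfig
    n_bits: int
    kind: str = "dlm"
    loss_curve: list[float] = field(default_factory=list)


@dataclass
class ErrorSummary:
    """Aggregate prediction errors with the per-molecule table behind them."""

    mean_rel_pct: float
    median_rel_pct: float
    mean_abs_s: float
    median_abs_s: float
    table: pd.DataFrame
    nonretained_excluded: bool
    n_excluded: int
    n: int


def split_train_val(
    records: list[MoleculeRecord],
    train_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Random disjoint, exhaustive train/validation split, reproducible by seed."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = [records[i] for i in perm[:n_train]]
    val = [records[i] for i in perm[n_train:]]
    return train, val


def _training_arrays(records: list[MoleculeRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise ValueError("empty training set")
    X = fingerprint_matrix(records).astype(np.float64)
    rts = [r.rt for r in records]
    if any(rt is None for rt in rts):
        raise ValueError("all training records need an rt")
    return X, np.asarray(rts, dtype=np.float64)


def train_dlm(records: list[MoleculeRecord], config: DlmConfig | None = None) -> RTModel:
    """Train the feed-forward RT network for exactly ``config.epochs`` passes.

    No early stopping or validation-based monitoring: the epoch count is a
    fixed schedule. The per-epoch training loss is kept on the returned model.
    Training is deterministic for a fixed ``config.seed`` in a single-threaded
    run.
    """
    config = config or DlmConfig()
    X, y = _training_arrays(records)
    est = MLPRegressor(
        hidden_layer_sizes=config.hidden_units,
        activation="relu",
        solver="adam",
        alpha=config.l2_lambda,
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(records)),
        max_iter=config.epochs,
        shuffle=True,
        random_state=config.seed,
        tol=0.0,
        n_iter_no_change=config.epochs + 1,
        early_stopping=False,
    )
    import warnings

    with warnings.catch_warnings():
        # the fixed epoch budget intentionally stops before convergence
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return RTModel(
        estimator=est,
        config=config,
        n_bits=X.shape[1],
        kind="dlm",
        loss_curve=list(est.loss_curve_),
    )


def train_rf_baseline(
    records: list[MoleculeRecord], n_trees: int = 100, seed: int = 0
) -> RTModel:
    """Random-forest comparator trained on the same fingerprints and target."""
    X, y = _training_arrays(records)
    est = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    est.fit(X, y)
    cfg = DlmConfig(seed=seed)
    return RTModel(estimator=est, config=cfg, n_bits=X.shape[1], kind="rf")


def predict_rt(model: RTModel, records: list[MoleculeRecord]) -> np.ndarray:
    """Predicted RT in seconds, one finite value per record."""
    if not records:
        return np.empty(0)
    X = fingerprint_matrix(records).astype(np.float64)
    if X.shape[1] != model.n_bits:
        raise ValueError(
            f"fingerprint length {X.shape[1]} does not match training length {model.n_bits}"
        )
    pred = np.asarray(model.estimator.predict(X), dtype=np.float64)
    if not np.isfinite(pred).all():
        raise RuntimeError("model produced non-finite predictions")
    return pred


def evaluate_errors(
    predicted: np.ndarray,
    experimental: np.ndarray,
    exclude_nonretained: bool = False,
    nonretained_cutoff: float = DEFAULT_NONRETAINED_CUTOFF,
    mol_ids: list[str] | None = None,
) -> ErrorSummary:
    """Per-molecule and aggregate RT prediction errors.

    Relative error is 100 * |predicted - experimental| / experimental; the
    experimental RT in the denominator makes errors comparable across early
    and late eluters. With ``exclude_nonretained`` set, molecules whose
    experimental RT falls below ``nonretained_cutoff`` are dropped from the
    summary and their count is reported.
    """
    pred = np.asarray(predicted, dtype=np.float64)
    exp = np.asarray(experimental, dtype=np.float64)
    if pred.shape != exp.shape:
        raise ValueError("predicted and experimental must be aligned")
    if (exp <= 0).any():
        raise ValueError("experimental RT must be > 0")
    ids = mol_ids if mol_ids is not None else [str(i) for i in range(len(pred))]
    table = pd.DataFrame(
        {
            "mol_id": ids,
            "rt_pred_s": pred,
            "rt_exp_s": exp,
            "abs_error_s": np.abs(pred - exp),
            "rel_error_pct": 100.0 * np.abs(pred - exp) / exp,
        }
    )
    n_excluded = 0
    if exclude_nonretained:
        keep = table["rt_exp_s"] >= nonretained_cutoff
        n_excluded = int((~keep).sum())
        table = table.loc[keep].reset_index(drop=True)
    if table.empty:
        raise ValueError("no molecules left to evaluate")
    return ErrorSummary(
        mean_rel_pct=float(table["rel_error_pct"].mean()),
        median_rel_pct=float(table["rel_error_pct"].median()),
        mean_abs_s=float(table["abs_error_s"].mean()),
        median_abs_s=float(table["abs_error_s"].median()),
        table=table,
        nonretained_excluded=exclude_nonretained,
        n_excluded=n_excluded,
        n=len(table),
    )


def detect_nonretained_cutoff(rts: np.ndarray, low_region: float = 600.0) -> float:
    """Largest-gap heuristic for the retained/non-retained boundary.

    Looks at experimental RTs below ``low_region`` seconds and places the
    cutoff in the middle of the widest gap between consecutive sorted values.
    Falls back to the default cutoff when fewer than two molecules elute in
    the low region.
    """
    low = np.sort(np.asarray(rts, dtype=np.float64))
    low = low[low <= low_region]
    if len(low) < 2:
        return DEFAULT_NONRETAINED_CUTOFF
    gaps = np.diff(low)
    i = int(np.argmax(gaps))
    return float((low[i] + low[i + 1]) / 2.0)
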
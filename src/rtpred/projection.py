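"""Projection of predicted RT onto another chromatographic method's scale.

Elution order is broadly conserved between reverse-phase methods, so the RT
predicted on the reference method can be mapped onto an external method by a
smooth one-dimensional function fitted on a handful of anchor molecules
identified in both. The map is a least-squares polynomial (degree 4 by
default) of experimental-on-predicted RT, fitted on an orthogonal/scaled
basis for numerical stability and serialised in the plain power basis. An
optional iteratively reweighted (Huber) mode damps aberrant predictions;
it is off by default.

Anchor subsets are drawn at random, so every fit records the anchor ids and
the seed used to draw them: re-fits with different subsets legitimately give
different projections, but any single fit is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from .dlm import ErrorSummary, evaluate_errors

DEFAULT_DEGREE = 4


@dataclass
class AnchorSet:
    """Molecules identified on both scales: predicted reference RT vs target RT."""

    ids: list[str]
    rt_pred: np.ndarray
    rt_exp: np.ndarray

    def __post_init__(self) -> None:
        self.rt_pred = np.asarray(self.rt_pred, dtype=np.float64)
        self.rt_exp = np.asarray(self.rt_exp, dtype=np.float64)
        if not (len(self.ids) == len(self.rt_pred) == len(self.rt_exp)):
            raise ValueError("anchor fields must be aligned")
        if not (np.isfinite(self.rt_pred).all() and np.isfinite(self.rt_exp).all()):
            raise ValueError("anchor RTs must be finite")


@dataclass
class ProjectionFn:
    """Fitted polynomial map from predicted reference RT to a target method."""

    degree: int
    poly: Polynomial
    anchor_ids: list[str]
    residuals: np.ndarray
    seed: int | None = None
    robust: bool = False

    @property
    def support(self) -> tuple[float, float]:
        """Predicted-RT range covered by the anchors (the fit's domain)."""
        lo, hi = self.poly.domain
        return float(lo), float(hi)

    @property
    def rms_residual(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))

    def coefficients(self) -> np.ndarray:
        """Coefficients in the plain power basis, ascending degree."""
        return self.poly.convert().coef

    def to_json(self, path: str) -> None:
        payload = {
            "degree": self.degree,
            "coefficients_power_basis": [float(c) for c in self.coefficients()],
            "anchor_ids": self.anchor_ids,
            "support": list(self.support),
            "rms_residual": self.rms_residual,
            "seed": self.seed,
            "robust": self.robust,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ProjectionFn":
        with open(path) as fh:
            payload = json.load(fh)
        poly = Polynomial(payload["coefficients_power_basis"])
        poly = poly.convert(domain=payload["support"], window=payload["support"])
        fn = cls(
            degree=payload["degree"],
            poly=poly,
            anchor_ids=payload["anchor_ids"],
            residuals=np.empty(0),
            seed=payload["seed"],
            robust=payload["robust"],
        )
        return fn


def select_anchors(ids: list[str], n_anchors: int = 50, seed: int = 0) -> list[str]:
    """Uniform random anchor subset without replacement, reproducible by seed."""
    if n_anchors > len(ids):
        raise ValueError(f"cannot draw {n_anchors} anchors from {len(ids)} molecules")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ids), size=n_anchors, replace=False)
    return [ids[i] for i in sorted(idx)]


def fit_projection(
    anchors: AnchorSet,
    degree: int = DEFAULT_DEGREE,
    robust: bool = False,
    seed: int | None = None,
) -> ProjectionFn:
    """Least-squares polynomial fit of target RT on predicted reference RT.

    Requires strictly more anchors than polynomial coefficients and at least
    degree+1 distinct predicted-RT values. ``robust=True`` runs a few rounds
    of Huber reweighting to downweight aberrant anchors.
    """
    n = len(anchors.ids)
    if n < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} anchors for a degree-{degree} fit, got {n}"
        )
    x, y = anchors.rt_pred, anchors.rt_exp
    if len(np.unique(x)) < degree + 1:
        raise ValueError("rank-deficient fit: too few distinct predicted-RT values")
    poly = Polynomial.fit(x, y, deg=degree)
    if robust:
        for _ in range(5):
            resid = y - poly(x)
            scale = 1.4826 * np.median(np.abs(resid)) + 1e-12
            w = np.minimum(1.0, 1.345 / (np.abs(resid) / scale + 1e-12))
            poly = Polynomial.fit(x, y, deg=degree, w=np.sqrt(w))
    return ProjectionFn(
        degree=degree,
        poly=poly,
        anchor_ids=list(anchors.ids),
        residuals=y - poly(x),
        seed=seed,
        robust=robust,
    )


def project_rt(
    fn: ProjectionFn, predicted: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the projection; flag values outside the anchor support.

    Returns ``(projected, extrapolated)`` where ``extrapolated`` marks inputs
    beyond the predicted-RT range of the anchors. Extrapolations are evaluated
    (the polynomial is defined everywhere), not clamped — the flag is the
    caller's cue to distrust them.
    """
    x = np.asarray(predicted, dtype=np.float64)
    lo, hi = fn.support
    return fn.poly(x), (x < lo) | (x > hi)


def projection_error_summary(
    projected: np.ndarray,
    experimental: np.ndarray,
    mol_ids: list[str] | None = None,
) -> ErrorSummary:
    """Error summary of projected vs experimental RT on the target scale.

    Same definitions as the reference-scale evaluation: relative error in %
    of the target method's experimental RT, absolute error in seconds.
    """
    return evaluate_errors(projected, experimental, mol_ids=mol_ids)
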
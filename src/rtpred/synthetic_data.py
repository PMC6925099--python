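"""Synthetic reverse-phase LC benchmark generator.

Emulates the statistical structure the pipeline assumes, at desk scale and
with no download:

* a molecule library whose binary fingerprints carry cluster/similarity
  structure (so similarity strata at 95/90/80/70/50% are all populated),
  plus a fraction of unclustered singletons with no close neighbour;
* retention time from a latent structure-to-RT map — sparse linear in
  fingerprint bits, optionally passed through a mild monotone nonlinearity —
  plus a per-cluster random offset (the similarity-dependent component:
  predictable only when structurally similar molecules are in the training
  set) and replicate noise (sd 18 s, the median replicate RT variability of
  the real acquisition it mimics);
* a non-retained fraction eluting in a band below the gradient start,
  separated from retained molecules by a clear RT gap;
* external chromatographic methods that are noisy strictly monotone warps
  (scaled beta CDF) of the reference RT scale, in short (<300 s) and long
  (>=1500 s) regimes, with a seeded subset of "identified" anchor molecules;
* query ions with known identities, with masses drawn so that a configurable
  share of molecules is within a few ppm of another (multi-candidate mass
  search is exercised).

Fingerprints are sampled directly; no chemically valid structures are
generated. Every generator is fully deterministic under its config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .molecules import MoleculeRecord, adduct_mz


@dataclass
class GeneratorConfig:
    """Knobs of the library generator. Defaults are the benchmark conditions."""

    n_molecules: int = 5000
    n_bits: int = 1024
    n_clusters: int = 1000
    centroid_density: float = 0.08
    flip_mean: float = 8.0  # mean bits flipped per molecule off its centroid
    background_fraction: float = 0.10  # unclustered singleton molecules
    n_active_bits: int = 150
    weight_sd: float = 85.0  # s per active bit
    rt_intercept: float = 750.0  # s
    rt_min: float = 320.0  # s, earliest retained elution
    rt_max: float = 1500.0  # s, end of gradient
    nonlinearity: str = "mild"  # "mild" (monotone tanh bend) or "linear"
    nonlin_gamma: float = 0.3
    nonlin_scale: float = 250.0  # s
    cluster_rt_sd: float = 25.0  # s, shared per-cluster RT offset
    rt_noise_sd: float = 18.0  # s, replicate variability
    nonretained_fraction: float = 0.05
    nonretained_range: tuple[float, float] = (25.0, 90.0)
    mass_range: tuple[float, float] = (80.0, 600.0)
    mass_collision_rate: float = 0.20  # share of molecules within collision_ppm of another
    collision_ppm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_fraction", "nonretained_fraction", "mass_collision_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rt_noise_sd < 0 or self.cluster_rt_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if self.n_molecules <= 0 or self.n_clusters <= 0:
            raise ValueError("n_molecules and n_clusters must be positive")
        if self.nonlinearity not in ("mild", "linear"):
            raise ValueError("nonlinearity must be 'mild' or 'linear'")
        if self.nonretained_range[1] >= self.rt_min:
            raise ValueError("non-retained band must sit below rt_min (the RT gap)")


@dataclass
class EcmConfig:
    """An external chromatographic method: a noisy monotone warp of reference RT."""

    warp: str = "beta"  # "beta" (scaled beta-CDF warp) or "identity"
    warp_a: float = 2.0
    warp_b: float = 1.3
    length_s: float = 1600.0  # short regime < 300 s, long regime >= 1500 s
    noise_sd: float | None = None  # defaults to 2% of length_s
    n_anchors: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warp not in ("beta", "identity"):
            raise ValueError("warp must be 'beta' or 'identity'")
        if self.warp_a <= 0 or self.warp_b <= 0:
            raise ValueError("beta warp parameters must be positive")
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")

    @property
    def effective_noise_sd(self) -> float:
        return 0.02 * self.length_s if self.noise_sd is None else self.noise_sd


@dataclass
class LibraryTruth:
    """The latent model behind a generated library, kept for recovery tests."""

    weights: np.ndarray
    intercept: float
    nonlinearity: str
    nonlin_gamma: float
    nonlin_scale: float
    cluster_labels: np.ndarray  # per molecule; singletons get unique labels
    cluster_offsets: np.ndarray  # per molecule, s
    rt_latent: np.ndarray  # noiseless retained-scale RT, s
    nonretained: np.ndarray  # boolean mask
    config: GeneratorConfig

    def to_json(self, path: str) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "nonlinearity": self.nonlinearity,
            "nonlin_gamma": self.nonlin_gamma,
            "nonlin_scale": self.nonlin_scale,
            "seed": self.config.seed,
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class EcmRealization:
    """One generated external method: full RT table, anchors and the true warp."""

    table: pd.DataFrame  # mol_id, rt_ecm_s
    anchor_ids: list[str]
    config: EcmConfig
    ref_scale: float  # reference RT normalisation used by the warp

    def warp_fn(self, rt_ref: np.ndarray) -> np.ndarray:
        """The true (noiseless) warp, for recovery tests."""
        return _warp(np.asarray(rt_ref, dtype=np.float64), self.config, self.ref_scale)


def _latent_map(X: np.ndarray, cfg: GeneratorConfig, w: np.ndarray) -> np.ndarray:
    z = X @ w + cfg.rt_intercept
    if cfg.nonlinearity == "mild":
        # monotone: derivative 1 + gamma * (1 - tanh^2) > 0
        z = z + cfg.nonlin_gamma * cfg.nonlin_scale * np.tanh(
            (z - cfg.rt_intercept) / cfg.nonlin_scale
        )
    return z


def gen_library(config: GeneratorConfig | None = None) -> tuple[list[MoleculeRecord], LibraryTruth]:
    """Generate a molecule library with fingerprints, masses and RTs.

    Clustered molecules are noisy copies of a cluster centroid fingerprint
    (geometric number of flipped bits), singletons are independent random
    fingerprints. RT = latent_map(fingerprint) + cluster offset + N(0, sd),
    clipped to the retained elution window. Non-retention is structural: the
    configured fraction with the lowest latent RT (the least-retained
    structures) elutes uniformly in the void band below the gradient start.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_molecules
    n_bg = int(round(cfg.background_fraction * n))
    n_cl = n - n_bg

    centroids = rng.random((cfg.n_clusters, cfg.n_bits)) < cfg.centroid_density
    labels_cl = rng.integers(0, cfg.n_clusters, n_cl)
    X_cl = centroids[labels_cl].copy()
    if cfg.flip_mean > 0 and n_cl:
        n_flip = rng.geometric(1.0 / cfg.flip_mean, n_cl) if cfg.flip_mean >= 1 else np.zeros(n_cl, int)
        for i in range(n_cl):
            idx = rng.integers(0, cfg.n_bits, n_flip[i])
            X_cl[i, idx] ^= True
    X_bg = rng.random((n_bg, cfg.n_bits)) < cfg.centroid_density
    labels_bg = cfg.n_clusters + np.arange(n_bg)

    X = np.vstack([X_cl, X_bg]) if n_bg else X_cl
    labels = np.concatenate([labels_cl, labels_bg])
    perm = rng.permutation(n)
    X, labels = X[perm], labels[perm]
    # guard against the (vanishingly rare) all-zero fingerprint
    empty = ~X.any(axis=1)
    if empty.any():
        X[np.where(empty)[0], rng.integers(0, cfg.n_bits, int(empty.sum()))] = True

    w = np.zeros(cfg.n_bits)
    active = rng.choice(cfg.n_bits, cfg.n_active_bits, replace=False)
    w[active] = rng.normal(0.0, cfg.weight_sd, cfg.n_active_bits)

    offsets_by_label = {
        lab: rng.normal(0.0, cfg.cluster_rt_sd) for lab in np.unique(labels)
    }
    offsets = np.array([offsets_by_label[lab] for lab in labels])

    rt_latent = np.clip(
        _latent_map(X.astype(np.float64), cfg, w) + offsets, cfg.rt_min, cfg.rt_max
    )
    rt = rt_latent + rng.normal(0.0, cfg.rt_noise_sd, n)

    # non-retention is structural, as on a real column: the least-retained
    # tail of the latent RT distribution elutes in the void band instead
    nonretained = np.zeros(n, dtype=bool)
    n_nr = int(round(cfg.nonretained_fraction * n))
    if n_nr:
        nonretained[np.argsort(rt_latent, kind="stable")[:n_nr]] = True
    rt[nonretained] = rng.uniform(*cfg.nonretained_range, int(nonretained.sum()))

    masses = rng.uniform(*cfg.mass_range, n)
    n_coll = int(round(cfg.mass_collision_rate * n))
    if n_coll and n > 1:
        targets = rng.choice(n, n_coll, replace=False)
        for i in targets:
            j = int(rng.integers(0, n - 1))
            j += j >= i
            masses[i] = masses[j] * (1.0 + rng.uniform(-cfg.collision_ppm, cfg.collision_ppm) * 1e-6)

    width = len(str(n - 1))
    records = [
        MoleculeRecord(
            mol_id=f"M{i:0{width}d}",
            fingerprint=X[i].astype(np.uint8),
            mono_mass=float(masses[i]),
            rt=float(rt[i]),
        )
        for i in range(n)
    ]
    truth = LibraryTruth(
        weights=w,
        intercept=cfg.rt_intercept,
        nonlinearity=cfg.nonlinearity,
        nonlin_gamma=cfg.nonlin_gamma,
        nonlin_scale=cfg.nonlin_scale,
        cluster_labels=labels,
        cluster_offsets=offsets,
        rt_latent=rt_latent,
        nonretained=nonretained,
        config=cfg,
    )
    return records, truth


def _warp(rt_ref: np.ndarray, cfg: EcmConfig, ref_scale: float) -> np.ndarray:
    if cfg.warp == "identity":
        return rt_ref.copy()
    x = np.clip(rt_ref / ref_scale, 0.0, 1.0)
    return cfg.length_s * beta_dist.cdf(x, cfg.warp_a, cfg.warp_b)


def gen_ecm(
    records: list[MoleculeRecord],
    truth: LibraryTruth,
    config: EcmConfig | None = None,
) -> EcmRealization:
    """Generate an external method's experimental RT table for retained molecules.

    Experimental RT = warp(true reference RT) + N(0, sd); the warp is a scaled
    beta CDF over the reference elution window, strictly increasing, so
    elution order is conserved (exactly so at zero noise). A seeded subset of
    molecules is marked as identified anchors.
    """
    cfg = config or EcmConfig()
    rng = np.random.default_rng(cfg.seed)
    retained = ~truth.nonretained
    ids = [r.mol_id for i, r in enumerate(records) if retained[i]]
    rt_ref = truth.rt_latent[retained]
    ref_scale = truth.config.rt_max
    rt_ecm = _warp(rt_ref, cfg, ref_scale) + rng.normal(0.0, cfg.effective_noise_sd, len(ids))
    rt_ecm = np.maximum(rt_ecm, 1.0)
    table = pd.DataFrame({"mol_id": ids, "rt_ecm_s": rt_ecm})
    if cfg.n_anchors > len(ids):
        raise ValueError(f"cannot draw {cfg.n_anchors} anchors from {len(ids)} molecules")
    anchor_idx = rng.choice(len(ids), cfg.n_anchors, replace=False)
    anchor_ids = [ids[i] for i in sorted(anchor_idx)]
    return EcmRealization(table=table, anchor_ids=anchor_ids, config=cfg, ref_scale=ref_scale)


def gen_query_ions(
    ecm: EcmRealization,
    records: list[MoleculeRecord],
    mass_noise_ppm: float = 0.5,
    n_queries: int | None = None,
    seed: int = 0,
):
    """One annotated ion per (sampled) molecule on the external method.

    The observed m/z is the molecule's protonated or deprotonated adduct m/z
    (random polarity) within +-``mass_noise_ppm`` of the exact value; the
    query RT is the molecule's experimental RT on the external method, and the
    true identity is recorded for evaluation.
    """
    from .annotate import QueryIon

    rng = np.random.default_rng(seed)
    by_id = {r.mol_id: r for r in records}
    table = ecm.table
    if n_queries is not None and n_queries < len(table):
        table = table.iloc[sorted(rng.choice(len(table), n_queries, replace=False))]
    queries = []
    for row in table.itertuples(index=False):
        rec = by_id[row.mol_id]
        adduct = "M+H" if rng.random() < 0.5 else "M-H"
        mz = adduct_mz(rec.mono_mass, adduct) * (
            1.0 + rng.uniform(-mass_noise_ppm, mass_noise_ppm) * 1e-6
        )
        queries.append(
            QueryIon(
                query_id=f"Q_{row.mol_id}",
                mz=float(mz),
                adduct=adduct,
                rt_exp=float(row.rt_ecm_s),
                true_mol_id=row.mol_id,
            )
        )
    return queries


def write_anchor_csv(ecm: EcmRealization, path: str) -> None:
    """PredRet-style anchor CSV (mol_id, rt_experimental_s) for the anchors."""
    sub = ecm.table[ecm.table["mol_id"].isin(ecm.anchor_ids)]
    sub = sub.rename(columns={"rt_ecm_s": "rt_experimental_s"})
    sub.to_csv(path, index=False)
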
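"""Structure I/O, circular fingerprints, Tanimoto similarity and mass arithmetic.

Shared vocabulary for the whole pipeline: molecules are carried as
:class:`MoleculeRecord` objects holding an id, an optional structure, a
fixed-length binary fingerprint, an optional monoisotopic neutral mass (Da)
and an optional retention time in seconds.

Fingerprints are Morgan (circular) fingerprints, the open-source equivalent
of extended connectivity fingerprints; the defaults (radius 2, 1024 bits)
correspond to ECFP4 as commonly used in QSRR modelling. Similarity is the
Tanimoto coefficient expressed as a percentage, 0 (disjoint substructure
sets) to 100 (identical fingerprints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

#: Mass of a proton in Da; the m/z offset of singly charged [M+H]+ / [M-H]- ions.
PROTON_MASS = 1.007276

DEFAULT_N_BITS = 1024
DEFAULT_RADIUS = 2


@dataclass
class MoleculeRecord:
    """One molecule: id, optional structure/mass/RT and a binary fingerprint.

    ``rt`` is in seconds, ``mono_mass`` is the neutral monoisotopic mass in Da.
    ``fingerprint`` is a 0/1 ``uint8`` vector; its length must be identical
    across a dataset (enforced where records are consumed in bulk).
    """

    mol_id: str
    structure: str | None = None
    fingerprint: np.ndarray | None = None
    mono_mass: float | None = None
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint)
            if not np.isin(fp, (0, 1)).all():
                raise ValueError(f"{self.mol_id}: fingerprint must be binary")
            self.fingerprint = fp.astype(np.uint8)
        if self.rt is not None and self.rt < 0:
            raise ValueError(f"{self.mol_id}: rt must be >= 0, got {self.rt}")
        if self.mono_mass is not None and self.mono_mass <= 0:
            raise ValueError(f"{self.mol_id}: mono_mass must be > 0")


@dataclass
class ParseReport:
    """Molecules read from a file plus an account of what failed to parse."""

    records: list[MoleculeRecord]
    failures: list[str] = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return len(self.failures)


def compute_fingerprint(
    structure: str | Chem.Mol,
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_RADIUS,
) -> np.ndarray:
    """Morgan fingerprint of a SMILES string or RDKit Mol as a 0/1 uint8 vector.

    Deterministic for a given structure and (n_bits, radius): the underlying
    hashing has no run-dependent state.
    """
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if isinstance(structure, Chem.Mol):
        mol = structure
    else:
        mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"invalid structure: {structure!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


def _records_from_smiles_frame(
    df: pd.DataFrame, n_bits: int, radius: int
) -> ParseReport:
    records: list[MoleculeRecord] = []
    failures: list[str] = []
    for row in df.itertuples(index=False):
        smiles = str(row.smiles)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            failures.append(f"{row.mol_id}: unparseable SMILES {smiles!r}")
            continue
        records.append(
            MoleculeRecord(
                mol_id=str(row.mol_id),
                structure=smiles,
                fingerprint=compute_fingerprint(mol, n_bits=n_bits, radius=radius),
                mono_mass=Descriptors.ExactMolWt(mol),
                rt=float(row.rt) if "rt" in df.columns and pd.notna(row.rt) else None,
            )
        )
    return ParseReport(records, failures)


def _read_smiles_csv(path: str, n_bits: int, radius: int) -> ParseReport:
    # Accept both a headered CSV (mol_id,smiles[,rt,mass]) and a bare
    # positional two/three-column file.
    head = pd.read_csv(path, header=None, nrows=1)
    first = str(head.iloc[0, 0]).strip().lower()
    if first in {"mol_id", "id"}:
        df = pd.read_csv(path)
        df = df.rename(columns={"id": "mol_id"})
    else:
        names = ["mol_id", "smiles", "rt", "mass"]
        df = pd.read_csv(path, header=None)
        df.columns = names[: df.shape[1]]
    if "smiles" not in df.columns:
        raise ValueError(f"{path}: no smiles column found")
    return _records_from_smiles_frame(df, n_bits, radius)


def _read_sdf(path: str, n_bits: int, radius: int) -> ParseReport:
    records: list[MoleculeRecord] = []
    failures: list[str] = []
    supplier = Chem.SDMolSupplier(path, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            failures.append(f"record {i}: unparseable SDF block")
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i}"
        rt = None
        for prop in ("RETENTION_TIME", "rt", "RT"):
            if mol.HasProp(prop):
                rt = float(mol.GetProp(prop))
                break
        records.append(
            MoleculeRecord(
                mol_id=mol_id,
                structure=Chem.MolToSmiles(mol),
                fingerprint=compute_fingerprint(mol, n_bits=n_bits, radius=radius),
                mono_mass=Descriptors.ExactMolWt(mol),
                rt=rt,
            )
        )
    return ParseReport(records, failures)


def _read_fp_csv(path: str) -> ParseReport:
    df = pd.read_csv(path)
    if "mol_id" not in df.columns:
        raise ValueError(f"{path}: fingerprint CSV needs a mol_id column")
    bit_cols = [c for c in df.columns if c.startswith("bit")]
    if not bit_cols:
        raise ValueError(f"{path}: no bit* columns found")
    fps = df[bit_cols].to_numpy()
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        records.append(
            MoleculeRecord(
                mol_id=str(row.mol_id),
                fingerprint=fps[i],
                mono_mass=float(row.mono_mass)
                if "mono_mass" in df.columns and pd.notna(row.mono_mass)
                else None,
                rt=float(row.rt) if "rt" in df.columns and pd.notna(row.rt) else None,
            )
        )
    return ParseReport(records, [])


def read_molecules(
    path: str,
    format: str,
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_RADIUS,
) -> ParseReport:
    """Read molecules from ``sdf``, ``smiles_csv`` or ``fp_csv`` files.

    Structure-bearing formats get fingerprints computed on the fly with the
    given parameters; ``fp_csv`` rows carry precomputed fingerprints and no
    structure. Unparseable entries are collected in ``ParseReport.failures``
    rather than silently dropped; a file with zero valid records raises.
    """
    readers = {
        "sdf": lambda: _read_sdf(path, n_bits, radius),
        "smiles_csv": lambda: _read_smiles_csv(path, n_bits, radius),
        "fp_csv": lambda: _read_fp_csv(path),
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    report = readers[format]()
    if not report.records:
        raise ValueError(f"{path}: no valid molecule records ({report.n_failed} failures)")
    return report


def write_fp_csv(records: list[MoleculeRecord], path: str) -> None:
    """Write records in the fingerprint-CSV dialect read_molecules consumes."""
    fps = fingerprint_matrix(records)
    df = pd.DataFrame(fps, columns=[f"bit{i}" for i in range(fps.shape[1])])
    df.insert(0, "mol_id", [r.mol_id for r in records])
    df.insert(1, "rt", [r.rt for r in records])
    df.insert(2, "mono_mass", [r.mono_mass for r in records])
    df.to_csv(path, index=False)


def fingerprint_matrix(records: list[MoleculeRecord]) -> np.ndarray:
    """Stack record fingerprints into an (n, n_bits) uint8 matrix.

    Raises if any record lacks a fingerprint or lengths are inconsistent.
    """
    fps = []
    for r in records:
        if r.fingerprint is None:
            raise ValueError(f"{r.mol_id}: no fingerprint")
        fps.append(r.fingerprint)
    lengths = {len(f) for f in fps}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
    return np.vstack(fps)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity of two binary vectors, in percent.

    100 * |a AND b| / |a OR b|. Undefined (raises) when both vectors are
    all-zero — an empty substructure set has no meaningful similarity.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return 100.0 * np.logical_and(a, b).sum() / union


def tanimoto_matrix(query_fps: np.ndarray, ref_fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarities (%), queries x references.

    Computed via the bit-count identity |a∩b| / (|a| + |b| - |a∩b|) with one
    matrix product. Pairs where both vectors are all-zero raise, as in
    :func:`tanimoto`.
    """
    q = np.asarray(query_fps, dtype=np.float64)
    r = np.asarray(ref_fps, dtype=np.float64)
    if q.shape[1] != r.shape[1]:
        raise ValueError("fingerprint length mismatch")
    inter = q @ r.T
    union = q.sum(axis=1)[:, None] + r.sum(axis=1)[None, :] - inter
    if (union == 0).any():
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return 100.0 * inter / union


def adduct_mz(mono_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct ion of a neutral monoisotopic mass.

    ``M+H`` adds one proton mass, ``M-H`` removes one. Unicode minus is
    accepted in the adduct label.
    """
    if mono_mass <= 0:
        raise ValueError("mono_mass must be > 0")
    label = adduct.replace("−", "-").replace("–", "-")
    if label == "M+H":
        return mono_mass + PROTON_MASS
    if label == "M-H":
        return mono_mass - PROTON_MASS
    raise ValueError(f"unknown adduct {adduct!r}; expected M+H or M-H")


def neutral_mass(mz: float, adduct: str) -> float:
    """Invert :func:`adduct_mz`: neutral monoisotopic mass from an ion m/z."""
    label = adduct.replace("−", "-").replace("–", "-")
    if label == "M+H":
        return mz - PROTON_MASS
    if label == "M-H":
        return mz + PROTON_MASS
    raise ValueError(f"unknown adduct {adduct!r}; expected M+H or M-H")


def ppm_error(obs_mz: float, theo_mz: float) -> float:
    """Absolute mass deviation in parts per million of the theoretical m/z."""
    if obs_mz <= 0 or theo_mz <= 0:
        raise ValueError("m/z values must be > 0")
    return 1e6 * abs(obs_mz - theo_mz) / theo_mz

def ppm_match(obs_mz: float, theo_mz: float, tol_ppm: float) -> bool:
    """True iff the observed m/z is within tol_ppm of the theoretical m/z.

    The tolerance window is relative to the theoretical ion m/z (the database
    value), the usual convention for accurate-mass search.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    return ppm_error(obs_mz, theo_mz) <= tol_ppm
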
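"""Retention-time regression from molecular structure.

Trains a random-forest regressor mapping physicochemical descriptors of a
SMILES structure to chromatographic retention time (minutes) on a
reversed-phase gradient, following the QSRR (quantitative structure
retention relationship) approach. The shipped training fixture carries the
46 reference analytes acquired on the standardized 25-minute C18 method.

Featurization is a pluggable, deterministic SMILES -> vector strategy; the
default uses a fixed panel of RDKit 2-D descriptors (size, lipophilicity,
polarity, hydrogen bonding, flexibility, aromaticity), which dominate
reversed-phase retention behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

__all__ = [
    "RTTrainingRecord",
    "RTModel",
    "RTMetrics",
    "FeaturizationError",
    "DESCRIPTOR_NAMES",
    "featurize",
    "train_rt_model",
    "predict_rt",
    "evaluate_rt_model",
    "delta_rt",
    "load_rt_training",
]


class FeaturizationError(ValueError):
    """Raised when a structure string cannot be parsed or featurized."""


#: Descriptor schema, version 1. Order is part of the model contract.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "MolWt",
    "MolLogP",
    "TPSA",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "NumAromaticRings",
    "RingCount",
    "FractionCSP3",
    "HeavyAtomCount",
    "NumHeteroatoms",
    "NumSaturatedRings",
    "LabuteASA",
    "MolMR",
    "BertzCT",
    "BalabanJ",
    "MaxPartialCharge",
    "MinPartialCharge",
)


def featurize(structure: str) -> np.ndarray:
    """Deterministic descriptor vector for a SMILES string.

    Raises :class:`FeaturizationError` for unparseable input; non-finite
    descriptor values (e.g. partial charges on exotic atoms) are zeroed so
    the vector is always finite.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise FeaturizationError(f"cannot parse structure {structure!r}")
    values = [
        Descriptors.MolWt(mol),
        Crippen.MolLogP(mol),
        rdMolDescriptors.CalcTPSA(mol),
        rdMolDescriptors.CalcNumHBD(mol),
        rdMolDescriptors.CalcNumHBA(mol),
        rdMolDescriptors.CalcNumRotatableBonds(mol),
        rdMolDescriptors.CalcNumAromaticRings(mol),
        rdMolDescriptors.CalcNumRings(mol),
        rdMolDescriptors.CalcFractionCSP3(mol),
        mol.GetNumHeavyAtoms(),
        rdMolDescriptors.CalcNumHeteroatoms(mol),
        rdMolDescriptors.CalcNumSaturatedRings(mol),
        rdMolDescriptors.CalcLabuteASA(mol),
        Crippen.MolMR(mol),
        Descriptors.BertzCT(mol),
        Descriptors.BalabanJ(mol),
        Descriptors.MaxPartialCharge(mol),
        Descriptors.MinPartialCharge(mol),
    ]
    vec = np.array(values, dtype=float)
    vec[~np.isfinite(vec)] = 0.0
    return vec


@dataclass(frozen=True)
class RTTrainingRecord:
    """One training analyte: name, structure and observed RT (minutes)."""

    compound_name: str
    structure: str
    rt_observed: float

    def __post_init__(self) -> None:
        if not (self.rt_observed > 0):
            raise ValueError(
                f"{self.compound_name!r}: observed RT must be positive"
            )


@dataclass
class RTModel:
    """A fitted descriptor -> RT regressor with its schema and provenance."""

    algorithm: str
    estimator: RandomForestRegressor
    descriptor_names: tuple[str, ...]
    n_train: int
    seed: int


def train_rt_model(
    records: Sequence[RTTrainingRecord],
    algorithm: str = "random_forest",
    seed: int = 0,
    n_estimators: int = 500,
) -> RTModel:
    """Fit a random forest on the featurized training records.

    Reproducible under a fixed seed. Featurization failures are collected
    and reported together.
    """
    if algorithm != "random_forest":
        raise ValueError(
            f"unsupported algorithm {algorithm!r}; only 'random_forest' "
            f"is provided"
        )
    if len(records) < 10:
        raise ValueError(
            f"need at least 10 training records, got {len(records)}"
        )
    failures = []
    X_rows, y = [], []
    for rec in records:
        try:
            X_rows.append(featurize(rec.structure))
        except FeaturizationError as exc:
            failures.append(str(exc))
            continue
        y.append(rec.rt_observed)
    if failures:
        raise FeaturizationError(
            f"{len(failures)} structure(s) failed to featurize:\n  "
            + "\n  ".join(failures)
        )
    return train_on_descriptors(
        np.vstack(X_rows), np.array(y), seed=seed,
        n_estimators=n_estimators, descriptor_names=DESCRIPTOR_NAMES,
    )


def train_on_descriptors(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_estimators: int = 500,
    descriptor_names: Sequence[str] | None = None,
) -> RTModel:
    """Fit the RT regressor directly on a descriptor matrix.

    The descriptor-level entry point behind :func:`train_rt_model`; also the
    natural hook for calibration studies on synthetic descriptor -> RT data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    est = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    est.fit(X, y)
    names = tuple(descriptor_names) if descriptor_names else tuple(
        f"x{i}" for i in range(X.shape[1])
    )
    return RTModel(
        algorithm="random_forest",
        estimator=est,
        descriptor_names=names,
        n_train=len(y),
        seed=seed,
    )


def predict_rt(model: RTModel, structure: str) -> float:
    """Predicted retention time (minutes, >= 0) for a SMILES string."""
    vec = featurize(structure).reshape(1, -1)
    return float(max(0.0, model.estimator.predict(vec)[0]))


@dataclass(frozen=True)
class RTMetrics:
    """Regression diagnostics on (predicted, observed) RT pairs."""

    rmse: float
    r2: float
    mae: float
    ci95: float


def evaluate_rt_model(
    pairs: Sequence[tuple[float, float]],
    ci_method: str = "abs_quantile",
) -> RTMetrics:
    """Compute RMSE, R², MAE and a 95% residual band from (pred, obs) pairs.

    ``ci95`` is the 95th percentile of |residuals| by default; pass
    ``ci_method="normal"`` for 1.96 x sd(residuals) instead.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 prediction pairs")
    pred = np.array([p for p, _ in pairs], dtype=float)
    obs = np.array([o for _, o in pairs], dtype=float)
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed RTs have zero variance; R² undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if ci_method == "abs_quantile":
        ci95 = float(np.quantile(np.abs(resid), 0.95))
    elif ci_method == "normal":
        ci95 = float(1.96 * np.std(resid, ddof=1))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RTMetrics(rmse=rmse, r2=r2, mae=mae, ci95=ci95)


def delta_rt(rt_pred: float, rt_obs: float) -> float:
    """Signed prediction error, predicted minus observed (minutes)."""
    return rt_pred - rt_obs


def load_rt_training(path: str | Path | None = None) -> pd.DataFrame:
    """Load the shipped 46-analyte RT training table (or a user CSV).

    Columns: ``compound_name``, ``smiles``, ``rt_predicted``,
    ``rt_observed``, ``delta_rt`` — predicted values from the original
    random-forest fit on the standardized gradient, observed values from
    extracted-ion chromatograms of the reference mixture.
    """
    if path is None:
        with resources.as_file(
            resources.files("hormonomics.data") / "rt_training_table.csv"
        ) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def training_records(df: pd.DataFrame) -> list[RTTrainingRecord]:
    """Convert a training table to records (rows without SMILES dropped)."""
    records = []
    for row in df.itertuples(index=False):
        smiles = getattr(row, "smiles", None)
        if smiles is None or (isinstance(smiles, float) and math.isnan(smiles)):
            continue
        records.append(RTTrainingRecord(
            compound_name=row.compound_name,
            structure=str(smiles),
            rt_observed=float(row.rt_observed),
        ))
    return records
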
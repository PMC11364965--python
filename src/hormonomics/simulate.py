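"""Synthetic peak tables with known ground truth.

Generates feature tables that emulate the input contract of the screening
pipeline: spiked features placed at the theoretical m/z of chosen
(compound, rule) pairs with Gaussian m/z and RT noise, plus decoy features
guaranteed to lie at least a chosen distance from every expanded-catalogue
m/z. Because the ground truth of every row is recorded, recall and false
annotation counts of a screen are measurable exactly.

All randomness flows from a single integer seed through one generator
stream. Draw order: for each spike in plan order, m/z noise, then RT noise,
then the per-sample log-normal intensities; then for each decoy, rejection-
sampled m/z, then RT, then intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from hormonomics.compounds import CompoundDatabase
from hormonomics.query import Annotation, Feature, FeatureTable
from hormonomics.shifts import (
    Mode,
    apply_shift,
    builtin_ruleset,
    expand_database,
    parse_shift,
)

__all__ = [
    "SpikePlan",
    "TruthRecord",
    "TruthManifest",
    "RecoveryScore",
    "generate_peak_table",
    "score_recovery",
]

# Fixed intensity model: log-normal(meanlog 10, sdlog 1). Intensities carry
# no information for matching; they exist to exercise the I/O contract.
_INTENSITY_MEANLOG = 10.0
_INTENSITY_SDLOG = 1.0

_DECOY_MZ_RANGE = (100.0, 1000.0)
_DECOY_RT_RANGE = (0.5, 20.0)
_MAX_DECOY_ATTEMPTS = 100_000


@dataclass(frozen=True)
class SpikePlan:
    """A planned true feature: compound x rule with noise magnitudes."""

    compound_name: str
    rule_label: str = "M"
    mz_noise_sd: float = 0.0
    rt_noise_sd: float = 0.0
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mz_noise_sd < 0 or self.rt_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.intensity_scale <= 0:
            raise ValueError("intensity scale must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated row."""

    row_index: int
    source: Literal["spike", "decoy"]
    compound_name: Optional[str] = None
    rule_label: Optional[str] = None
    true_mz: Optional[float] = None
    true_rt: Optional[float] = None


@dataclass
class TruthManifest:
    """Per-row ground truth covering every generated feature exactly once."""

    records: list[TruthRecord]

    def spikes(self) -> list[TruthRecord]:
        return [r for r in self.records if r.source == "spike"]

    def decoys(self) -> list[TruthRecord]:
        return [r for r in self.records if r.source == "decoy"]


def generate_peak_table(
    db: CompoundDatabase,
    plans: Sequence[SpikePlan],
    n_decoys: int = 0,
    decoy_min_distance: float = 0.05,
    n_samples: int = 3,
    seed: int = 0,
    mode: Mode = "neutral_shift",
    default_rt: float = 5.0,
) -> tuple[FeatureTable, TruthManifest]:
    """Generate a peak table of spiked true features plus decoys.

    Spike m/z is theoretical m/z + N(0, mz_noise_sd); spike RT is the parent
    compound's predicted RT (or ``default_rt`` when absent) + N(0,
    rt_noise_sd). Decoy m/z is uniform over [100, 1000], rejection-sampled
    until at least ``decoy_min_distance`` from every m/z of the catalogue
    expanded under ALL built-in rule sets, so false annotations are
    attributable to the matcher rather than to decoy placement.
    """
    rng = np.random.default_rng(seed)

    # Exclusion list: the catalogue under every built-in rule set. Rules
    # inapplicable to light parents are silently absent (nothing to avoid).
    import warnings

    forbidden: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in ("monoisotopic", "mh", "adducts", "biotransformations"):
            forbidden.extend(
                e.theoretical_mz
                for e in expand_database(db, builtin_ruleset(name), mode)
            )
    forbidden_arr = np.sort(np.array(forbidden))

    features: list[Feature] = []
    records: list[TruthRecord] = []
    row = 0
    for plan in plans:
        compound = db.get(plan.compound_name)
        rule = parse_shift(plan.rule_label)
        true_mz = apply_shift(compound.monoisotopic_mass, rule, mode)
        true_rt = (
            compound.predicted_rt
            if compound.predicted_rt is not None
            else default_rt
        )
        mz = true_mz + rng.normal(0.0, plan.mz_noise_sd) if plan.mz_noise_sd else true_mz
        rt = max(0.0, true_rt + rng.normal(0.0, plan.rt_noise_sd)) if plan.rt_noise_sd else true_rt
        intens = tuple(
            plan.intensity_scale
            * rng.lognormal(_INTENSITY_MEANLOG, _INTENSITY_SDLOG)
            for _ in range(n_samples)
        )
        features.append(Feature(mz=mz, rt=rt, intensities=intens, row_index=row))
        records.append(TruthRecord(
            row_index=row, source="spike", compound_name=compound.name,
            rule_label=rule.label, true_mz=true_mz, true_rt=true_rt,
        ))
        row += 1

    for _ in range(n_decoys):
        for attempt in range(_MAX_DECOY_ATTEMPTS):
            mz = rng.uniform(*_DECOY_MZ_RANGE)
            i = np.searchsorted(forbidden_arr, mz)
            near = []
            if i > 0:
                near.append(forbidden_arr[i - 1])
            if i < len(forbidden_arr):
                near.append(forbidden_arr[i])
            if all(abs(mz - f) >= decoy_min_distance for f in near):
                break
        else:
            raise RuntimeError(
                "decoy placement failed: catalogue too dense for the "
                f"requested minimum distance {decoy_min_distance} Da"
            )
        rt = rng.uniform(*_DECOY_RT_RANGE)
        intens = tuple(
            rng.lognormal(_INTENSITY_MEANLOG, _INTENSITY_SDLOG)
            for _ in range(n_samples)
        )
        features.append(Feature(mz=mz, rt=rt, intensities=intens, row_index=row))
        records.append(TruthRecord(row_index=row, source="decoy",
                                   true_mz=mz, true_rt=rt))
        row += 1

    sample_names = [f"sample_{i + 1}" for i in range(n_samples)]
    table = FeatureTable(features, sample_names, source=f"synthetic(seed={seed})")
    return table, TruthManifest(records)


@dataclass(frozen=True)
class RecoveryScore:
    """Recall over spiked pairs and false annotations on decoy rows.

    ``recall`` is None when the run contained no spikes.
    """

    recall: Optional[float]
    false_annotation_count: int
    n_spikes: int
    n_recovered: int


def score_recovery(
    annotations: Sequence[Annotation],
    manifest: TruthManifest,
) -> RecoveryScore:
    """Score a screen of a generated table against its ground truth.

    A spike counts as recovered when some annotation on its own row carries
    its (compound, rule) pair. Every annotation landing on a decoy row is a
    false annotation.
    """
    known_rows = {r.row_index for r in manifest.records}
    for a in annotations:
        if a.feature.row_index not in known_rows:
            raise ValueError(
                f"annotation on row {a.feature.row_index} not covered by the "
                f"truth manifest"
            )
    annotated: dict[int, set[tuple[str, str]]] = {}
    for a in annotations:
        annotated.setdefault(a.feature.row_index, set()).add(
            (a.entry.compound.name, a.entry.rule.label)
        )
    spikes = manifest.spikes()
    recovered = sum(
        1
        for r in spikes
        if (r.compound_name, r.rule_label) in annotated.get(r.row_index, set())
    )
    decoy_rows = {r.row_index for r in manifest.decoys()}
    false_count = sum(
        1 for a in annotations if a.feature.row_index in decoy_rows
    )
    return RecoveryScore(
        recall=(recovered / len(spikes)) if spikes else None,
        false_annotation_count=false_count,
        n_spikes=len(spikes),
        n_recovered=recovered,
    )
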
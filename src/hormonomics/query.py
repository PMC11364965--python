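"""Peak-table ingestion and m/z + retention-time annotation.

The screening algorithm is two-stage: features are first matched to expanded
database entries on m/z within a user tolerance (± Da or ppm), then the
matches for each feature are ranked by how close the observed retention time
is to the predicted retention time of the parent compound (the "%RT match").
Annotations carry MSI (Metabolomics Standards Initiative) level 3: two
physicochemical properties, no reference-standard confirmation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from hormonomics.compounds import Compound, CompoundDatabase
from hormonomics.shifts import (
    Mode,
    RuleSet,
    ShiftedEntry,
    builtin_ruleset,
    expand_database,
)

__all__ = [
    "Feature",
    "FeatureTable",
    "Tolerance",
    "Annotation",
    "PeakTableError",
    "read_peak_table",
    "tolerance_in_da",
    "rt_match_percent",
    "match_features",
    "rank_annotations",
    "dedup_compounds",
    "match_rate",
    "screen",
    "annotations_to_frame",
]

#: Default upload ceiling for peak tables (10 MiB); overridable per call.
DEFAULT_MAX_BYTES = 10 * 1024 * 1024


class PeakTableError(ValueError):
    """Raised for malformed or oversized peak-table files."""


@dataclass(frozen=True)
class Feature:
    """One peak-table row: observed m/z, retention time, sample intensities."""

    mz: float
    rt: float
    intensities: tuple[float, ...] = ()
    row_index: int = 0

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise PeakTableError(f"row {self.row_index}: m/z must be positive")
        if self.rt < 0:
            raise PeakTableError(f"row {self.row_index}: RT must be >= 0")


@dataclass
class FeatureTable:
    """Ordered feature list plus the sample names of the intensity columns."""

    features: list[Feature] = field(default_factory=list)
    sample_names: list[str] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


def read_peak_table(
    path: str | Path, max_bytes: int = DEFAULT_MAX_BYTES
) -> FeatureTable:
    """Read a peak-table CSV: column 1 m/z, column 2 RT (min), columns 3+
    per-sample intensities. A header row is required; row order is preserved.
    """
    path = Path(path)
    size = path.stat().st_size
    if size > max_bytes:
        raise PeakTableError(
            f"{path.name}: {size} bytes exceeds the {max_bytes} byte limit "
            f"(pass max_bytes to raise it)"
        )
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise PeakTableError(
            f"{path.name}: need at least m/z and RT columns, got {df.shape[1]}"
        )
    if df.empty:
        warnings.warn(f"{path.name}: header-only peak table, 0 features",
                      stacklevel=2)
        return FeatureTable([], list(df.columns[2:]), str(path))

    features = []
    for i, row in enumerate(df.itertuples(index=False, name=None)):
        try:
            mz, rt = float(row[0]), float(row[1])
        except (TypeError, ValueError):
            raise PeakTableError(
                f"{path.name}: non-numeric m/z or RT in data row {i}"
            ) from None
        intens = tuple(float(v) if pd.notna(v) else 0.0 for v in row[2:])
        features.append(Feature(mz=mz, rt=rt, intensities=intens, row_index=i))
    return FeatureTable(features, list(df.columns[2:]), str(path))


@dataclass(frozen=True)
class Tolerance:
    """A mass-match window: value in Da (absolute) or ppm (relative)."""

    value: float
    unit: Literal["Da", "ppm"] = "Da"

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValueError("tolerance must be positive")
        if self.unit not in ("Da", "ppm"):
            raise ValueError(f"unknown tolerance unit {self.unit!r}")


def tolerance_in_da(tol: Tolerance, at_mz: float) -> float:
    """Absolute window in Da; ppm tolerances are evaluated at ``at_mz``
    (the theoretical, database-side m/z)."""
    if tol.unit == "Da":
        return tol.value
    return at_mz * tol.value / 1e6


def rt_match_percent(rt_obs: float, rt_pred: float) -> float:
    """Closeness of observed to predicted RT as a percentage.

    100 x (1 - |rt_obs - rt_pred| / rt_pred), clipped to [0, 100]. 100 iff
    the two agree exactly; 0 once the deviation reaches the predicted RT
    itself.
    """
    if rt_pred <= 0:
        raise ValueError("predicted RT must be positive to score an RT match")
    return max(0.0, 100.0 * (1.0 - abs(rt_obs - rt_pred) / rt_pred))


@dataclass(frozen=True)
class Annotation:
    """A feature <-> shifted-entry match at MSI identification level 3."""

    feature: Feature
    entry: ShiftedEntry
    delta_mz: float  # observed - theoretical
    rt_match_pct: Optional[float] = None
    msi_level: int = 3


def match_features(
    table: FeatureTable | Sequence[Feature],
    entries: Sequence[ShiftedEntry],
    tol: Tolerance,
) -> list[Annotation]:
    """All (feature, entry) pairs with |mz_obs - mz_theo| <= tolerance.

    The boundary is inclusive and ppm windows are evaluated at the
    theoretical m/z. One feature may match several isobaric entries; all are
    returned, ordered by feature then by entry.
    """
    features = list(table)
    if not features or not entries:
        return []

    theo = np.array([e.theoretical_mz for e in entries])
    order = np.argsort(theo, kind="stable")
    theo_sorted = theo[order]
    # widest possible window, used only to pre-select candidates
    if tol.unit == "Da":
        halfwidth = tol.value
    else:
        halfwidth = float(theo_sorted[-1]) * tol.value / 1e6

    annots: list[Annotation] = []
    for feat in features:
        lo = np.searchsorted(theo_sorted, feat.mz - halfwidth, side="left")
        hi = np.searchsorted(theo_sorted, feat.mz + halfwidth, side="right")
        hits = []
        for idx in order[lo:hi]:
            entry = entries[idx]
            if abs(feat.mz - entry.theoretical_mz) <= tolerance_in_da(
                tol, entry.theoretical_mz
            ):
                hits.append(int(idx))
        for idx in sorted(hits):
            entry = entries[idx]
            rt_pct = None
            if entry.predicted_rt is not None and entry.predicted_rt > 0:
                rt_pct = rt_match_percent(feat.rt, entry.predicted_rt)
            annots.append(Annotation(
                feature=feat,
                entry=entry,
                delta_mz=feat.mz - entry.theoretical_mz,
                rt_match_pct=rt_pct,
            ))
    return annots


def _rank_key(a: Annotation):
    has_rt = a.rt_match_pct is not None
    return (
        a.feature.row_index,
        0 if has_rt else 1,
        -(a.rt_match_pct or 0.0),
        abs(a.delta_mz),
        a.entry.compound.name,
    )


def rank_annotations(annots: Sequence[Annotation]) -> list[Annotation]:
    """Sort by feature row, then descending %RT match; annotations without a
    predicted RT sort last within their feature, tie-broken by |delta m/z|
    then compound name. A permutation of the input."""
    return sorted(annots, key=_rank_key)


def dedup_compounds(annots: Sequence[Annotation]) -> list[Annotation]:
    """Keep the best-ranked annotation per (compound name, rule label) pair.

    Output order follows the first occurrence of each pair in the input, so
    applying this to ranked input keeps it ranked. Idempotent.
    """
    best: dict[tuple[str, str], Annotation] = {}
    first_seen: list[tuple[str, str]] = []
    for a in annots:
        key = (a.entry.compound.name, a.entry.rule.label)
        if key not in best:
            best[key] = a
            first_seen.append(key)
        elif _rank_key(a) < _rank_key(best[key]):
            best[key] = a
    return [best[k] for k in first_seen]


def match_rate(
    annots: Sequence[Annotation],
    references: Sequence[Compound] | Sequence[tuple[str, float]],
    tol: Tolerance,
) -> float:
    """Percentage of deduplicated annotations whose feature m/z matches some
    reference compound's m/z within tolerance, relative to the number of
    references. May exceed 100 when isobaric entries multiply-match.
    """
    if not references:
        raise ValueError("reference list must be non-empty")
    ref_mzs = [
        r.monoisotopic_mass if isinstance(r, Compound) else float(r[1])
        for r in references
    ]
    deduped = dedup_compounds(annots)
    hits = sum(
        1
        for a in deduped
        if any(
            abs(a.feature.mz - mz) <= tolerance_in_da(tol, mz) for mz in ref_mzs
        )
    )
    return 100.0 * hits / len(references)


def annotations_to_frame(
    annots: Sequence[Annotation], sample_names: Sequence[str] = ()
) -> pd.DataFrame:
    """Tabulate annotations with the screener-output column set."""
    rows = []
    for a in annots:
        row = {
            "Compound name": a.entry.compound.name,
            "Biotransformation": a.entry.rule.label,
            "Actual m/z": a.entry.theoretical_mz,
            "Experimental m/z": a.feature.mz,
            "Experimental RT": a.feature.rt,
            "Predicted RT": a.entry.predicted_rt,
            "%RT match": a.rt_match_pct,
            "dm/z": a.delta_mz,
            "MSI level": a.msi_level,
        }
        for name, value in zip(sample_names, a.feature.intensities):
            row[name] = value
        rows.append(row)
    columns = [
        "Compound name", "Biotransformation", "Actual m/z", "Experimental m/z",
        "Experimental RT", "Predicted RT", "%RT match", "dm/z", "MSI level",
        *sample_names,
    ]
    return pd.DataFrame(rows, columns=columns)


def screen(
    peaks: FeatureTable | str | Path,
    db: CompoundDatabase,
    ruleset: RuleSet | str = "mh",
    tol: Tolerance = Tolerance(0.02, "Da"),
    mode: Mode = "neutral_shift",
    dedup: bool = False,
    include_unannotated: bool = False,
) -> pd.DataFrame:
    """Full screening pipeline: read -> expand -> match -> rank -> tabulate.

    ``peaks`` may be a CSV path or an already-loaded :class:`FeatureTable`.
    ``ruleset`` is a :class:`RuleSet` or a built-in name/alias. Defaults
    mirror the conventional validation run: the M+H rule set at ±0.02 Da.
    """
    table = peaks if isinstance(peaks, FeatureTable) else read_peak_table(peaks)
    if isinstance(ruleset, str):
        ruleset = builtin_ruleset(ruleset)
    entries = expand_database(db, ruleset, mode)
    annots = rank_annotations(match_features(table, entries, tol))
    if dedup:
        annots = dedup_compounds(annots)
    frame = annotations_to_frame(annots, table.sample_names)
    if include_unannotated:
        matched_rows = {a.feature.row_index for a in annots}
        extra = []
        for feat in table:
            if feat.row_index not in matched_rows:
                extra.append({
                    "Compound name": None,
                    "Biotransformation": None,
                    "Actual m/z": None,
                    "Experimental m/z": feat.mz,
                    "Experimental RT": feat.rt,
                    **dict(zip(table.sample_names, feat.intensities)),
                })
        if extra:
            frame = pd.concat(
                [frame, pd.DataFrame(extra)], ignore_index=True
            )
    return frame
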
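"""Multi-study screening: retention-rule filtering and class summaries.

Public metabolomics repositories archive peak tables acquired under
heterogeneous chromatography, so annotations from different studies cannot
be filtered by one retention-time criterion. The retention rules here encode
a graded trust policy keyed on how each study's gradient relates to the
reference method the RT predictions were trained on:

* same gradient and column            -> keep %RT match > 70
* different gradient/column           -> keep %RT match > 50
* gradient not reported               -> keep 1 min < RT < column
                                         re-equilibration start
* direct injection (no column)        -> keep everything

After filtering, duplicate compound hits are removed and the surviving
compounds are binned by hormone class into a class x study count matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from hormonomics.compounds import CompoundDatabase
from hormonomics.query import (
    Annotation,
    Tolerance,
    dedup_compounds,
    match_features,
    rank_annotations,
    read_peak_table,
)
from hormonomics.shifts import Mode, RuleSet, builtin_ruleset, expand_database

__all__ = [
    "StudyConfig",
    "ClassSummary",
    "DEFAULT_REEQUILIBRATION_START",
    "apply_retention_rules",
    "screen_study",
    "class_summary",
    "read_manifest",
]

logger = logging.getLogger(__name__)

GradientStatus = Literal[
    "same_as_reference", "different", "not_provided", "direct_injection"
]

#: Default start of column re-equilibration (min) on the reference 25-minute
#: gradient: the last compositional ramp ends at 20 min and the final
#: isocratic hold re-equilibrates the column; analytes eluting in the ramp
#: back to initial conditions (>15 min) are not interpretable.
DEFAULT_REEQUILIBRATION_START = 15.0


@dataclass(frozen=True)
class StudyConfig:
    """One archived study: identity, acquisition mode and peak-table path."""

    study_id: str
    species: str
    ionization: Literal["ESI_pos", "ESI_neg", "both"]
    gradient_status: GradientStatus
    peak_table_path: str
    reequil_start: float = DEFAULT_REEQUILIBRATION_START

    def __post_init__(self) -> None:
        if not self.study_id.strip():
            raise ValueError("study_id must be non-empty")


def apply_retention_rules(
    annots: Sequence[Annotation],
    cfg: StudyConfig,
    reequil_start: float | None = None,
) -> list[Annotation]:
    """Filter ranked annotations by the study's gradient-trust rule.

    Thresholds are strict inequalities. Where a %RT-match threshold applies
    but an annotation has no %RT match (the parent compound lacks a
    predicted RT), the annotation is dropped with a warning.
    """
    limit = cfg.reequil_start if reequil_start is None else reequil_start
    status = cfg.gradient_status
    if status == "direct_injection":
        return list(annots)
    kept: list[Annotation] = []
    missing_rt = 0
    for a in annots:
        if status == "not_provided":
            if 1.0 < a.feature.rt < limit:
                kept.append(a)
            continue
        threshold = 70.0 if status == "same_as_reference" else 50.0
        if a.rt_match_pct is None:
            missing_rt += 1
            continue
        if a.rt_match_pct > threshold:
            kept.append(a)
    if missing_rt:
        warnings.warn(
            f"{cfg.study_id}: dropped {missing_rt} annotation(s) without a "
            f"%RT match where a threshold rule applies",
            stacklevel=2,
        )
    return kept


def screen_study(
    cfg: StudyConfig,
    db: CompoundDatabase,
    ruleset: RuleSet | str = "mh",
    tol: Tolerance = Tolerance(0.02, "Da"),
    mode: Mode = "neutral_shift",
) -> list[Annotation]:
    """Screen one study: match -> rank -> retention-rule filter -> dedup.

    Defaults follow the conventional repository screen: the M+H rule set at
    ±0.02 Da. An unreadable peak table skips the study (empty result) with a
    logged reason rather than failing the whole analysis.
    """
    try:
        table = read_peak_table(cfg.peak_table_path)
    except (OSError, ValueError) as exc:
        logger.warning("skipping study %s: %s", cfg.study_id, exc)
        return []
    if isinstance(ruleset, str):
        ruleset = builtin_ruleset(ruleset)
    entries = expand_database(db, ruleset, mode)
    annots = rank_annotations(match_features(table, entries, tol))
    return dedup_compounds(apply_retention_rules(annots, cfg))


@dataclass
class ClassSummary:
    """Distinct-compound counts per (hormone class, study), plus catalogue
    totals per class."""

    counts: pd.DataFrame  # index: class, columns: study ids
    database_totals: pd.Series  # index: class

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "database_total", self.database_totals)
        return out

    def to_long(self) -> pd.DataFrame:
        long = (
            self.counts.stack()
            .rename("count")
            .rename_axis(["class", "study_id"])
            .reset_index()
        )
        return long


def class_summary(
    per_study: Mapping[str, Sequence[Annotation]],
    db: CompoundDatabase,
) -> ClassSummary:
    """Bin each study's deduplicated compounds by hormone class.

    Counts distinct compound names per (class, study); compounds whose class
    is unknown to the catalogue are binned as ``"unclassified"`` with a
    warning. Invariant to annotation order.
    """
    if not per_study:
        raise ValueError("need at least one study")
    class_of = {c.name: c.hormone_class for c in db}
    totals = pd.Series(db.class_counts(), dtype=int).sort_index()

    studies = list(per_study)
    all_classes = set(totals.index)
    cells: dict[str, dict[str, int]] = {s: {} for s in studies}
    unclassified = 0
    for study, annots in per_study.items():
        names = {a.entry.compound.name for a in annots}
        for name in names:
            cls = class_of.get(name)
            if cls is None:
                cls = "unclassified"
                unclassified += 1
            all_classes.add(cls)
            cells[study][cls] = cells[study].get(cls, 0) + 1
    if unclassified:
        warnings.warn(
            f"{unclassified} compound(s) not in the catalogue binned as "
            f"'unclassified'",
            stacklevel=2,
        )
    index = sorted(all_classes)
    counts = pd.DataFrame(
        {s: [cells[s].get(cls, 0) for cls in index] for s in studies},
        index=pd.Index(index, name="class"),
        dtype=int,
    )
    totals = totals.reindex(index, fill_value=0)
    return ClassSummary(counts=counts, database_totals=totals)


def read_manifest(path: str | Path) -> list[StudyConfig]:
    """Read a study manifest CSV: ``study_id,species,ionization,
    gradient_status,peak_table_path[,reequil_start]``. Relative peak-table
    paths resolve against the manifest's directory."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"study_id", "species", "ionization", "gradient_status",
                "peak_table_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing manifest column(s) {sorted(missing)}")
    configs = []
    for row in df.itertuples(index=False):
        peak_path = Path(str(row.peak_table_path))
        if not peak_path.is_absolute():
            peak_path = path.parent / peak_path
        reequil = getattr(row, "reequil_start", None)
        configs.append(StudyConfig(
            study_id=str(row.study_id),
            species=str(row.species),
            ionization=str(row.ionization),
            gradient_status=str(row.gradient_status),
            peak_table_path=str(peak_path),
            reequil_start=(
                float(reequil)
                if reequil is not None and pd.notna(reequil)
                else DEFAULT_REEQUILIBRATION_START
            ),
        ))
    return configs
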
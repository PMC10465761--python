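"""Candidate filter funnel: connectivity class -> market status -> BBB -> docking.

The funnel mirrors a repositioning screen's attrition cascade. Drugs
with negative or zero connectivity are retained (both reversal and
neutrality are admissible for a repositioning hypothesis), then only
approved or nutraceutical compounds (safety record), then only drugs
annotated as blood–brain-barrier permeable (a CNS prerequisite), and
finally only drugs whose docking energy is strictly better (more
negative, kcal/mol) than the marketed standard at EVERY receptor.

Default standards are the marketed anti-epileptics carbamazepine
(Nav1.2, -7.13), clonazepam (GABA alpha1-beta1, -6.14) and pregabalin
(Cav3.1, -5.76 kcal/mol).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .connectivity import ConnectivityRecord
from .errors import FunnelOrderError, MissingStandardError

Status = Literal["approved", "nutraceutical", "experimental", "investigational", "withdrawn", "unknown"]
BBBLabel = Literal["permeable", "impermeable", "unknown"]

STATUS_VOCAB = frozenset(
    {"approved", "nutraceutical", "experimental", "investigational", "withdrawn", "unknown"}
)
BBB_VOCAB = frozenset({"permeable", "impermeable", "unknown"})
RECEPTORS = ("Nav1.2", "GABAr_a1b1", "Cav3.1")

DEFAULT_KEEP_CLASSES = frozenset({"negative", "zero"})
DEFAULT_KEEP_STATUS = frozenset({"approved", "nutraceutical"})


@dataclass(frozen=True)
class DrugAnnotation:
    drug_id: str
    status: Status = "unknown"
    bbb: BBBLabel = "unknown"

    def __post_init__(self) -> None:
        if self.status not in STATUS_VOCAB:
            raise ValueError(f"unknown status {self.status!r} for {self.drug_id!r}")
        if self.bbb not in BBB_VOCAB:
            raise ValueError(f"unknown bbb label {self.bbb!r} for {self.drug_id!r}")


@dataclass(frozen=True)
class DockingRecord:
    drug_id: str
    receptor_id: str
    binding_energy: float  # kcal/mol; more negative = stronger


@dataclass(frozen=True)
class StandardReference:
    receptor_id: str
    standard_drug: str
    binding_energy: float


DEFAULT_STANDARDS = (
    StandardReference("Nav1.2", "carbamazepine", -7.13),
    StandardReference("GABAr_a1b1", "clonazepam", -6.14),
    StandardReference("Cav3.1", "pregabalin", -5.76),
)


@dataclass
class FunnelStage:
    name: str
    drug_ids: list[str]
    class_breakdown: dict[str, int]

    @property
    def count(self) -> int:
        return len(self.drug_ids)


@dataclass
class FunnelReport:
    """Stage-by-stage retained sets; each stage a subset of its predecessor."""

    stages: list[FunnelStage]
    config: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {s.name: s.count for s in self.stages}

    def to_dict(self) -> dict:
        return {
            "stages": {
                s.name: {
                    "count": s.count,
                    "class_breakdown": s.class_breakdown,
                    "drug_ids": s.drug_ids,
                }
                for s in self.stages
            },
            "stage_order": [s.name for s in self.stages],
            "config": self.config,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        rows = [
            {"stage": s.name, "count": s.count, **{f"n_{k}": v for k, v in sorted(s.class_breakdown.items())}}
            for s in self.stages
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def select_by_connectivity(
    records: Sequence[ConnectivityRecord],
    keep_classes: frozenset = DEFAULT_KEEP_CLASSES,
) -> set[str]:
    """Retain drugs whose connectivity class is in ``keep_classes``."""
    if len(records) == 0:
        raise ValueError("no connectivity records to filter")
    return {r.drug_id for r in records if r.cls in keep_classes}


def filter_status(
    drugs: Iterable[str],
    annotations: Mapping[str, DrugAnnotation],
    keep: frozenset = DEFAULT_KEEP_STATUS,
) -> set[str]:
    """Retain drugs with an admissible market status.

    Drugs absent from the annotation table count as status unknown and
    are dropped — no safety record, no candidate.
    """
    return {d for d in drugs if d in annotations and annotations[d].status in keep}


def filter_bbb(drugs: Iterable[str], annotations: Mapping[str, DrugAnnotation]) -> set[str]:
    """Retain only drugs annotated as BBB permeable (unknown drops)."""
    return {d for d in drugs if d in annotations and annotations[d].bbb == "permeable"}


def select_better_than_standard(
    docking: Sequence[DockingRecord],
    standards: Sequence[StandardReference] = DEFAULT_STANDARDS,
    require_all: bool = True,
    drugs: Iterable[str] | None = None,
) -> tuple[set[str], dict[str, int]]:
    """Drugs with strictly better (more negative) energy than the standard.

    With ``require_all`` a drug must beat the standard at every receptor
    (a tie is not better; a missing energy excludes). Returns the
    retained set and per-receptor better-than-standard counts. ``drugs``
    optionally restricts the candidate pool.
    """
    std = {s.receptor_id: s.binding_energy for s in standards}
    pool = None if drugs is None else set(drugs)
    energies: dict[str, dict[str, float]] = {}
    for rec in docking:
        if pool is not None and rec.drug_id not in pool:
            continue
        if rec.receptor_id not in std:
            raise MissingStandardError(f"no standard for receptor {rec.receptor_id!r}")
        energies.setdefault(rec.drug_id, {})[rec.receptor_id] = rec.binding_energy

    per_receptor = {r: 0 for r in std}
    retained: set[str] = set()
    for drug, by_rec in energies.items():
        beats = {r for r, e in by_rec.items() if e < std[r]}
        for r in beats:
            per_receptor[r] += 1
        if require_all:
            if beats == set(std):
                retained.add(drug)
        elif beats:
            retained.add(drug)
    return retained, per_receptor


def build_funnel_report(
    stage_outputs: Sequence[tuple[str, Iterable[str]]],
    class_of: Mapping[str, str] | None = None,
    config: dict | None = None,
) -> FunnelReport:
    """Assemble and validate the stage report.

    Raises ``FunnelOrderError`` if any stage is not a subset of its
    predecessor — that always indicates a pipeline bug, not bad data.
    """
    stages: list[FunnelStage] = []
    prev: set[str] | None = None
    for name, ids in stage_outputs:
        id_set = set(ids)
        if prev is not None and not id_set.issubset(prev):
            extra = sorted(id_set - prev)
            raise FunnelOrderError(f"stage {name!r} adds drugs not in its predecessor: {extra[:5]}")
        breakdown: dict[str, int] = {}
        if class_of is not None:
            for d in id_set:
                c = class_of.get(d, "unknown")
                breakdown[c] = breakdown.get(c, 0) + 1
        stages.append(FunnelStage(name=name, drug_ids=sorted(id_set), class_breakdown=breakdown))
        prev = id_set
    return FunnelReport(stages=stages, config=config or {})


def read_annotations(path) -> dict[str, DrugAnnotation]:
    """Read a CSV with header drug_id,status,bbb into a lookup table."""
    df = pd.read_csv(path, dtype=str).fillna("unknown")
    out: dict[str, DrugAnnotation] = {}
    for row in df.itertuples(index=False):
        if row.drug_id in out:
            raise ValueError(f"duplicate annotation for drug {row.drug_id!r}")
        out[row.drug_id] = DrugAnnotation(row.drug_id, row.status, row.bbb)
    return out


def read_docking(path) -> list[DockingRecord]:
    """Read a CSV with header drug_id,receptor_id,binding_energy."""
    df = pd.read_csv(path, dtype={"drug_id": str, "receptor_id": str})
    return [
        DockingRecord(r.drug_id, r.receptor_id, float(r.binding_energy))
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations: Iterable[DrugAnnotation], path) -> None:
    df = pd.DataFrame(
        [{"drug_id": a.drug_id, "status": a.status, "bbb": a.bbb} for a in annotations]
    )
    df.to_csv(path, index=False)


def write_docking(records: Iterable[DockingRecord], path) -> None:
    df = pd.DataFrame(
        [
            {"drug_id": r.drug_id, "receptor_id": r.receptor_id, "binding_energy": r.binding_energy}
            for r in records
        ]
    )
    df.to_csv(path, index=False, float_format="%.6g")
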
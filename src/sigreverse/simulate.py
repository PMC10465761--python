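"""Synthetic inputs with known ground truth for every pipeline stage.

Generates two-group expression matrices with planted up/down genes, a
perturbation library with planted reversers / mimics / concordant
drugs / nulls, annotation tables (market status, BBB permeability) and
docking-energy tables with planted winners. Everything is a pure
function of (config, seed): one global seed is threaded through the
sub-generators with fixed offsets, so identical configs reproduce
identical bundles byte for byte.

Noise is Normal throughout — the standard log2-scale microarray
assumption. ``funnel_study`` builds a full study-scale bundle whose
class / status / BBB / docking margins follow the reference epilepsy
repositioning funnel (1219 scored; 309 negative, 690 zero, 220
positive; 999 selected; 434 approved-or-nutraceutical; 323 BBB
permeable; 41 beating all three docking standards) by exact-count
allocation rather than sampling, so the funnel arithmetic is
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import PerturbationProfile
from .errors import InvalidConfigError
from .filtering import (
    DEFAULT_STANDARDS,
    DockingRecord,
    DrugAnnotation,
    StandardReference,
    write_annotations,
    write_docking,
)
from .signature import ExpressionMatrix

# seed offsets for the sub-generators (one global seed, fixed streams)
_EXPR_STREAM = 11
_PERT_STREAM = 23
_ANNOT_STREAM = 37
_DOCK_STREAM = 53

DrugRole = str  # reverser | mimic | null | concordant


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Expression defaults are the recovery conditions the screen is
    validated at: 20 vs 20 samples, 50 planted up and 50 planted down
    genes with a one-unit log2 effect over sigma = 0.3 noise.
    """

    n_genes: int = 2000
    n_case: int = 20
    n_control: int = 20
    n_up: int = 50
    n_down: int = 50
    effect: float = 1.0  # log2 units
    sigma_expr: float = 0.3
    mu_base: float = 7.0  # typical log2 microarray intensity
    baseline_sd: float = 1.0

    n_reversers: int = 30
    n_mimics: int = 20
    n_nulls: int = 50
    n_concordant: int = 0
    reversal_strength: float = 1.0  # alpha in [0, 1]
    sigma_pert: float = 0.5

    status_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "approved": 0.423,
            "nutraceutical": 0.011,
            "experimental": 0.074,
            "investigational": 0.040,
            "withdrawn": 0.055,
            "unknown": 0.397,
        }
    )
    bbb_rate: float = 0.744
    docking_mu_offset: float = 1.0  # mean energy relative to each standard
    docking_sd: float = 1.0
    n_planted_winners: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_case, self.n_control, self.n_up, self.n_down,
            self.n_reversers, self.n_mimics, self.n_nulls, self.n_concordant,
            self.n_planted_winners,
        )
        if any(c < 0 for c in counts):
            raise InvalidConfigError("all counts must be >= 0")
        if self.n_up + self.n_down > self.n_genes:
            raise InvalidConfigError("n_up + n_down exceeds n_genes")
        if not 0.0 <= self.reversal_strength <= 1.0:
            raise InvalidConfigError("reversal_strength must lie in [0, 1]")
        if abs(sum(self.status_proportions.values()) - 1.0) > 1e-9:
            raise InvalidConfigError("status proportions must sum to 1")
        if self.seed is None:
            raise InvalidConfigError("seed is mandatory")

    @property
    def n_drugs(self) -> int:
        return self.n_reversers + self.n_mimics + self.n_nulls + self.n_concordant


@dataclass
class GroundTruth:
    """Planted structure: which genes/drugs carry signal."""

    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)
    drug_roles: dict[str, DrugRole] = field(default_factory=dict)
    winners: list[str] = field(default_factory=list)

    def planted_effect(self, effect: float) -> dict[str, float]:
        out = {g: effect for g in self.up_genes}
        out.update({g: -effect for g in self.down_genes})
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Two-group log2 matrix with planted differential genes.

    Per gene g: baseline mu_g ~ Normal(mu_base, baseline_sd); each value
    is mu_g + Normal(0, sigma_expr); planted up genes gain +effect in
    cases, planted down genes -effect.
    """
    rng = _rng(config, _EXPR_STREAM)
    width = len(str(config.n_genes))
    genes = [f"gene{str(i + 1).zfill(width)}" for i in range(config.n_genes)]
    samples = [f"case{i + 1:03d}" for i in range(config.n_case)] + [
        f"ctrl{i + 1:03d}" for i in range(config.n_control)
    ]
    planted = rng.choice(config.n_genes, size=config.n_up + config.n_down, replace=False)
    up_idx, down_idx = planted[: config.n_up], planted[config.n_up :]

    mu = rng.normal(config.mu_base, config.baseline_sd, size=config.n_genes)
    values = mu[:, None] + rng.normal(
        0.0, config.sigma_expr, size=(config.n_genes, config.n_case + config.n_control)
    )
    values[up_idx, : config.n_case] += config.effect
    values[down_idx, : config.n_case] -= config.effect

    df = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control, index=samples
    )
    truth = GroundTruth(
        up_genes=sorted(genes[i] for i in up_idx),
        down_genes=sorted(genes[i] for i in down_idx),
    )
    return ExpressionMatrix(df, groups), truth


_ROLE_SIGN = {"reverser": -1.0, "mimic": 1.0, "null": 0.0}


def simulate_perturbation_library(
    config: SimulationConfig, truth: GroundTruth
) -> list[PerturbationProfile]:
    """Library with planted roles relative to the planted disease effect.

    Per drug and gene: stat = role_sign * alpha * planted_effect(gene)
    + Normal(0, sigma_pert). Reversers apply the opposite of the disease
    effect (role_sign = -1), mimics the same (+1), nulls pure noise.
    Concordant drugs apply |planted_effect| — both disease tag sets are
    pushed up together, which the same-sign rule scores as a structural
    zero. Roles are recorded in ``truth.drug_roles``.
    """
    rng = _rng(config, _PERT_STREAM)
    genes = sorted(set(truth.up_genes) | set(truth.down_genes))
    if config.n_genes < len(genes):
        raise InvalidConfigError("config.n_genes smaller than the planted signature")
    width = len(str(config.n_drugs))
    drug_ids = [f"drug{str(i + 1).zfill(width)}" for i in range(config.n_drugs)]
    roles = (
        ["reverser"] * config.n_reversers
        + ["concordant"] * config.n_concordant
        + ["mimic"] * config.n_mimics
        + ["null"] * config.n_nulls
    )
    rng.shuffle(roles)
    truth.drug_roles = dict(zip(drug_ids, roles))

    # gene universe: same ids as the expression matrix
    all_genes = _gene_universe(config)
    effect = truth.planted_effect(config.effect)
    base = np.array([effect.get(g, 0.0) for g in all_genes])
    alpha = config.reversal_strength

    profiles: list[PerturbationProfile] = []
    for drug_id, role in zip(drug_ids, roles):
        if role == "concordant":
            signal = alpha * np.abs(base)
        else:
            signal = _ROLE_SIGN[role] * alpha * base
        stats = signal + rng.normal(0.0, config.sigma_pert, size=len(all_genes))
        profiles.append(PerturbationProfile.from_stats(drug_id, dict(zip(all_genes, stats))))
    return profiles


def _gene_universe(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"gene{str(i + 1).zfill(width)}" for i in range(config.n_genes)]


def _exact_counts(proportions: dict[str, float], total: int) -> dict[str, int]:
    """Largest-remainder allocation of `total` items to the proportions."""
    raw = {k: proportions[k] * total for k in sorted(proportions)}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    by_frac = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def simulate_annotations(
    config: SimulationConfig,
    drug_ids: list[str],
    status_counts: dict[str, int] | None = None,
    n_permeable: int | None = None,
) -> list[DrugAnnotation]:
    """Status and BBB labels over the library.

    By default counts derive from ``status_proportions`` / ``bbb_rate``
    via largest-remainder rounding (exact totals, not sampling), then
    are assigned to seed-shuffled drugs. ``status_counts`` may instead
    fix exact per-status counts; drugs beyond their sum are left
    unannotated (absent rows — downstream treats them as unknown).
    """
    rng = _rng(config, _ANNOT_STREAM)
    if status_counts is None:
        status_counts = _exact_counts(config.status_proportions, len(drug_ids))
    total = sum(status_counts.values())
    if total > len(drug_ids):
        raise InvalidConfigError("status counts exceed library size")
    order = list(drug_ids)
    rng.shuffle(order)
    annotated = order[:total]
    statuses: list[str] = []
    for status in sorted(status_counts):
        statuses.extend([status] * status_counts[status])

    if n_permeable is None:
        n_permeable = int(round(config.bbb_rate * total))
    if n_permeable > total:
        raise InvalidConfigError("n_permeable exceeds annotated drugs")
    bbb_order = list(annotated)
    rng.shuffle(bbb_order)
    permeable = set(bbb_order[:n_permeable])

    return [
        DrugAnnotation(d, s, "permeable" if d in permeable else "impermeable")
        for d, s in zip(annotated, statuses)
    ]


def simulate_docking(
    config: SimulationConfig,
    drug_ids: list[str],
    standards: tuple[StandardReference, ...] = DEFAULT_STANDARDS,
    truth: GroundTruth | None = None,
) -> list[DockingRecord]:
    """Docking energies with ``n_planted_winners`` forced winners.

    Winners get standard - |offset| at every receptor; every other drug
    is clamped to at least one receptor at or above its standard, so the
    all-receptor filter retains exactly the planted winners.
    """
    if config.n_planted_winners > len(drug_ids):
        raise InvalidConfigError("n_planted_winners exceeds library size")
    rng = _rng(config, _DOCK_STREAM)
    order = list(drug_ids)
    rng.shuffle(order)
    winners = set(order[: config.n_planted_winners])
    if truth is not None:
        truth.winners = sorted(winners)

    records: list[DockingRecord] = []
    for drug in drug_ids:
        if drug in winners:
            for std in standards:
                margin = abs(rng.normal(0.5, 0.2)) + 0.05
                records.append(DockingRecord(drug, std.receptor_id, round(std.binding_energy - margin, 3)))
        else:
            energies = {
                std.receptor_id: rng.normal(
                    std.binding_energy + config.docking_mu_offset, config.docking_sd
                )
                for std in standards
            }
            # guarantee failure at >= 1 receptor
            std_by_rec = {s.receptor_id: s.binding_energy for s in standards}
            if all(energies[r] < std_by_rec[r] for r in energies):
                rec = rng.choice(sorted(energies))
                energies[rec] = std_by_rec[rec] + abs(rng.normal(0.5, 0.2)) + 0.05
            for rec, e in sorted(energies.items()):
                records.append(DockingRecord(drug, rec, round(float(e), 3)))
    return records


def write_expression(matrix: ExpressionMatrix, matrix_path, groups_path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.6f")
    pd.DataFrame({"sample_id": matrix.groups.index, "group": matrix.groups.values}).to_csv(
        groups_path, index=False
    )


def write_perturbation_matrix(profiles: list[PerturbationProfile], path) -> None:
    genes = sorted(profiles[0].stats)
    df = pd.DataFrame(
        [[p.stats[g] for g in genes] for p in profiles],
        index=[p.drug_id for p in profiles],
        columns=genes,
    )
    df.index.name = "drug_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


def simulate_bundle(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write the full input bundle + ground truth; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_expression(config)
    profiles = simulate_perturbation_library(config, truth)
    drug_ids = [p.drug_id for p in profiles]
    annotations = simulate_annotations(config, drug_ids)
    docking = simulate_docking(config, drug_ids, truth=truth)

    paths = {
        "expression": out / "expression.tsv",
        "groups": out / "groups.csv",
        "perturbation": out / "perturbation.tsv",
        "annotations": out / "annotations.csv",
        "docking": out / "docking.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_expression(matrix, paths["expression"], paths["groups"])
    write_perturbation_matrix(profiles, paths["perturbation"])
    write_annotations(annotations, paths["annotations"])
    write_docking(docking, paths["docking"])
    truth.to_json(paths["ground_truth"])
    return paths


# ---------------------------------------------------------------------------
# Study-scale funnel bundle with exact-count allocation
# ---------------------------------------------------------------------------

#: Printed funnel margins of the reference epilepsy repositioning screen.
FUNNEL_MARGINS = {
    "n_scored": 1219,
    "n_negative": 309,
    "n_zero": 690,
    "n_positive": 220,
    "n_selected": 999,
    "n_safe": 434,
    "n_bbb": 323,
    "n_final": 41,
    "n_final_negative": 21,
    "n_final_zero": 20,
    "better_per_receptor": {"Nav1.2": 128, "GABAr_a1b1": 59, "Cav3.1": 242},
}

# Joint allocations consistent with every printed margin (the joint
# tables themselves are not published): status x class over the 999
# selected drugs, and receptor-subsets-beaten over the 323 docked drugs.
_STATUS_BY_CLASS = {
    # status: (n_negative_class, n_zero_class)
    "approved": (130, 293),
    "nutraceutical": (4, 7),
    "experimental": (23, 51),
    "investigational": (12, 28),
    "withdrawn": (17, 38),
    "unknown": (3, 6),
    # remaining 120 negative + 267 zero drugs carry no annotation row
}
_BBB_PERMEABLE_BY_CLASS = {"negative": 102, "zero": 221}
_WINNERS_BY_CLASS = {"negative": 21, "zero": 20}
# receptor subsets beaten by the 282 permeable non-winners
_NONWINNER_SUBSETS = [
    (("Nav1.2", "GABAr_a1b1"), 18),
    (("Nav1.2", "Cav3.1"), 69),
    (("Cav3.1",), 132),
    ((), 63),
]


@dataclass
class FunnelStudy:
    """The generated study-scale inputs plus their ground truth."""

    config: SimulationConfig
    expression: ExpressionMatrix
    truth: GroundTruth
    profiles: list[PerturbationProfile]
    annotations: list[DrugAnnotation]
    docking: list[DockingRecord]
    standards: tuple[StandardReference, ...]


def funnel_study(seed: int = 0, n_genes: int = 500) -> FunnelStudy:
    """Build the full study-scale bundle by exact-count allocation.

    The library holds 309 reversers, 690 concordant drugs and 220
    mimics over ``n_genes`` genes with a 50/50 planted signature, so
    KS scoring reproduces the class margins structurally. Status, BBB
    and docking tables are allocated per the joint tables above. All
    assignment orderings are seed-shuffled; the counts are exact.
    """
    config = SimulationConfig(
        n_genes=n_genes,
        n_case=20,
        n_control=20,
        n_up=50,
        n_down=50,
        effect=1.0,
        sigma_expr=0.3,
        n_reversers=FUNNEL_MARGINS["n_negative"],
        n_concordant=FUNNEL_MARGINS["n_zero"],
        n_mimics=FUNNEL_MARGINS["n_positive"],
        n_nulls=0,
        reversal_strength=1.0,
        sigma_pert=0.1,
        seed=seed,
    )
    expression, truth = simulate_expression(config)
    profiles = simulate_perturbation_library(config, truth)

    rng = _rng(config, _ANNOT_STREAM)
    by_class: dict[str, list[str]] = {"negative": [], "zero": [], "positive": []}
    cls_of_role = {"reverser": "negative", "concordant": "zero", "mimic": "positive"}
    for drug, role in truth.drug_roles.items():
        by_class[cls_of_role[role]].append(drug)
    neg = sorted(by_class["negative"])
    zero = sorted(by_class["zero"])
    rng.shuffle(neg)
    rng.shuffle(zero)

    annotations: list[DrugAnnotation] = []
    safe_by_class: dict[str, list[str]] = {"negative": [], "zero": []}
    ptr = {"negative": 0, "zero": 0}
    pools = {"negative": neg, "zero": zero}
    for status in sorted(_STATUS_BY_CLASS):
        n_neg, n_zero = _STATUS_BY_CLASS[status]
        for cls, n in (("negative", n_neg), ("zero", n_zero)):
            pool = pools[cls]
            chosen = pool[ptr[cls] : ptr[cls] + n]
            ptr[cls] += n
            if status in ("approved", "nutraceutical"):
                safe_by_class[cls].extend(chosen)
            for d in chosen:
                annotations.append(DrugAnnotation(d, status, "impermeable"))

    # BBB: flip the chosen safe drugs to permeable
    permeable: set[str] = set()
    for cls, n_perm in _BBB_PERMEABLE_BY_CLASS.items():
        pool = sorted(safe_by_class[cls])
        rng.shuffle(pool)
        permeable.update(pool[:n_perm])
    annotations = [
        DrugAnnotation(a.drug_id, a.status, "permeable" if a.drug_id in permeable else a.bbb)
        for a in annotations
    ]

    # docking over the permeable drugs only (the study docked the 323)
    dock_rng = _rng(config, _DOCK_STREAM)
    winners: list[str] = []
    remaining: list[str] = []
    for cls, n_win in _WINNERS_BY_CLASS.items():
        pool = sorted(d for d in permeable if d in set(safe_by_class[cls]))
        dock_rng.shuffle(pool)
        winners.extend(pool[:n_win])
        remaining.extend(pool[n_win:])
    truth.winners = sorted(winners)
    dock_rng.shuffle(remaining)

    std_by_rec = {s.receptor_id: s.binding_energy for s in DEFAULT_STANDARDS}
    docking: list[DockingRecord] = []

    def emit(drug: str, beaten: tuple[str, ...]) -> None:
        for rec, std_e in std_by_rec.items():
            if rec in beaten:
                e = std_e - (0.2 + 1.3 * dock_rng.random())
            else:
                e = std_e + (0.1 + 1.4 * dock_rng.random())
            docking.append(DockingRecord(drug, rec, round(e, 3)))

    for drug in winners:
        emit(drug, tuple(std_by_rec))
    idx = 0
    for subset, count in _NONWINNER_SUBSETS:
        for drug in remaining[idx : idx + count]:
            emit(drug, subset)
        idx += count
    assert idx == len(remaining)

    return FunnelStudy(
        config=config,
        expression=expression,
        truth=truth,
        profiles=profiles,
        annotations=annotations,
        docking=docking,
        standards=DEFAULT_STANDARDS,
    )


def write_funnel_study(study: FunnelStudy, out_dir) -> dict[str, Path]:
    """Serialise a funnel study to the standard input-bundle formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "groups": out / "groups.csv",
        "perturbation": out / "perturbation.tsv",
        "annotations": out / "annotations.csv",
        "docking": out / "docking.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_expression(study.expression, paths["expression"], paths["groups"])
    write_perturbation_matrix(study.profiles, paths["perturbation"])
    write_annotations(study.annotations, paths["annotations"])
    write_docking(study.docking, paths["docking"])
    study.truth.to_json(paths["ground_truth"])
    return paths
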
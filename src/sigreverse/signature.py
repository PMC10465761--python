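"""Disease-signature extraction from a two-group expression matrix.

The screen mirrors the classic microarray workflow: per-gene Welch
unequal-variance t-test on log2 intensities, a linear fold-change
threshold applied symmetrically (``2**|log2FC| > fc_min``), and a raw
p-value cut-off. Genes passing both cuts form the ordered up/down tag
sets used downstream for connectivity scoring.

Thresholds default to FC > 1.3 and p < 0.1 (both strict), the settings
used for the idiopathic-epilepsy contrast this pipeline models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import (
    DuplicateGeneError,
    EmptyMatrixError,
    GroupSizeError,
    NonNumericValueError,
    UnknownSampleError,
)

Direction = Literal["up", "down", "not_significant"]

DEFAULT_FC_MIN = 1.3
DEFAULT_P_MAX = 0.1


@dataclass
class ExpressionMatrix:
    """Log2 intensities, genes x samples, with a case/control design.

    ``values`` is a genes-by-samples DataFrame; ``groups`` maps every
    sample id to ``"case"`` or ``"control"``. Invariants (unique ids,
    finite values, >= 2 samples per group, complete labelling) are
    checked at construction.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise EmptyMatrixError("expression matrix has no genes or no samples")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise DuplicateGeneError(f"duplicate gene id(s): {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            raise UnknownSampleError("duplicate sample id in matrix columns")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise NonNumericValueError("expression matrix contains non-finite values")
        matrix_samples = set(self.values.columns)
        labelled = set(self.groups.index)
        if labelled - matrix_samples:
            missing = sorted(labelled - matrix_samples)
            raise UnknownSampleError(f"unknown sample in groups file: {missing[:5]}")
        if matrix_samples - labelled:
            missing = sorted(matrix_samples - labelled)
            raise UnknownSampleError(f"sample(s) without group label: {missing[:5]}")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise UnknownSampleError(f"group labels must be case/control, got {sorted(bad)}")
        for grp in ("case", "control"):
            n = int((self.groups == grp).sum())
            if n < 2:
                raise GroupSizeError(f"group '{grp}' has {n} sample(s); >= 2 required")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def swap_labels(self) -> "ExpressionMatrix":
        """Return a copy with case and control labels exchanged."""
        flipped = self.groups.map({"case": "control", "control": "case"})
        return ExpressionMatrix(self.values.copy(), flipped)


@dataclass(frozen=True)
class DifferentialRecord:
    gene_id: str
    log2_fc: float
    fold_change: float
    p_value: float
    direction: Direction


@dataclass
class DiseaseSignature:
    """Ordered up/down tag sets surviving the FC/p screen.

    Lists are sorted by ascending p-value, ties broken by descending
    fold change then lexical gene id, so outputs are deterministic.
    """

    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)
    fc_min: float = DEFAULT_FC_MIN
    p_max: float = DEFAULT_P_MAX

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"gene(s) in both up and down sets: {sorted(overlap)[:5]}")

    @property
    def is_empty(self) -> bool:
        return not self.up_genes or not self.down_genes


def read_expression(
    matrix_path,
    groups_path,
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV and a (sample_id, group) CSV.

    The matrix file's first column must be ``gene_id``; remaining
    columns are sample ids. Column order is preserved. Set
    ``log2_transform`` for linear-scale input (applies log2(x + 1)).
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique()
        raise DuplicateGeneError(f"duplicate gene id(s) in {matrix_path}: {list(dupes)[:5]}")
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise NonNumericValueError(f"non-numeric cell in {matrix_path}: {exc}") from exc
    if log2_transform:
        values = np.log2(values + 1.0)
    grp = pd.read_csv(groups_path, dtype=str)
    expected = {"sample_id", "group"}
    if not expected.issubset(grp.columns):
        raise UnknownSampleError(f"groups file must have columns {sorted(expected)}")
    groups = pd.Series(grp["group"].values, index=grp["sample_id"].values)
    return ExpressionMatrix(values, groups)


def _welch_arrays(case: np.ndarray, control: np.ndarray):
    """Row-wise Welch t-test; returns (t, p) arrays.

    Zero-variance rows follow the degenerate-case convention: equal
    means -> (0, 1); unequal means -> (+/-inf, 0).
    """
    na, nb = case.shape[1], control.shape[1]
    ma, mb = case.mean(axis=1), control.mean(axis=1)
    va, vb = case.var(axis=1, ddof=1), control.var(axis=1, ddof=1)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = va / na + vb / nb
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    if np.any(degenerate):
        equal = degenerate & (diff == 0)
        unequal = degenerate & (diff != 0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        t = np.where(unequal, np.where(diff > 0, np.inf, -np.inf), t)
        p = np.where(unequal, 0.0, p)
    return t, p


def welch_t(case_values: Iterable[float], control_values: Iterable[float]):
    """Two-sided Welch unequal-variance t-test.

    Returns ``(t_statistic, p_value)`` with Welch-Satterthwaite degrees
    of freedom. Both groups need >= 2 finite values.
    """
    a = np.asarray(list(case_values), dtype=float)
    b = np.asarray(list(control_values), dtype=float)
    if a.size < 2 or b.size < 2:
        raise GroupSizeError("each group needs >= 2 values for Welch's t-test")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise NonNumericValueError("non-finite value passed to welch_t")
    t, p = _welch_arrays(a[None, :], b[None, :])
    return float(t[0]), float(p[0])


def compute_differential(
    expr: ExpressionMatrix,
    fc_min: float = DEFAULT_FC_MIN,
    p_max: float = DEFAULT_P_MAX,
    p_adjust: bool = False,
) -> tuple[list[DifferentialRecord], DiseaseSignature]:
    """Run the per-gene screen and assemble the disease signature.

    A gene passes iff ``2**|log2FC| > fc_min`` and ``p < p_max`` (both
    strict); direction follows the sign of log2FC (case minus control).
    With ``p_adjust``, the threshold is applied to Benjamini-Hochberg
    adjusted p-values instead of raw ones. An all-filtered screen
    returns an empty signature with a warning, not an error.
    """
    if not fc_min > 1:
        raise ValueError(f"fc_min must exceed 1, got {fc_min}")
    if not 0 < p_max <= 1:
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    case = expr.values[expr.samples_in("case")].to_numpy(dtype=float)
    control = expr.values[expr.samples_in("control")].to_numpy(dtype=float)
    _, p = _welch_arrays(case, control)
    log2_fc = case.mean(axis=1) - control.mean(axis=1)
    fold_change = 2.0 ** np.abs(log2_fc)
    p_screen = multipletests(p, method="fdr_bh")[1] if p_adjust else p

    records: list[DifferentialRecord] = []
    passing: list[tuple[float, float, str, str]] = []
    for i, gene in enumerate(expr.gene_ids):
        passed = fold_change[i] > fc_min and p_screen[i] < p_max
        if passed:
            direction: Direction = "up" if log2_fc[i] > 0 else "down"
            passing.append((p_screen[i], -fold_change[i], gene, direction))
        else:
            direction = "not_significant"
        records.append(
            DifferentialRecord(gene, float(log2_fc[i]), float(fold_change[i]), float(p[i]), direction)
        )
    passing.sort()
    up = [g for _, _, g, d in passing if d == "up"]
    down = [g for _, _, g, d in passing if d == "down"]
    signature = DiseaseSignature(up, down, fc_min=fc_min, p_max=p_max)
    if signature.is_empty:
        warnings.warn("screen produced an empty signature (no up or no down genes)", stacklevel=2)
    return records, signature


def write_differential(records: list[DifferentialRecord], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2_fc": [r.log2_fc for r in records],
            "fold_change": [r.fold_change for r in records],
            "p_value": [r.p_value for r in records],
            "direction": [r.direction for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
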
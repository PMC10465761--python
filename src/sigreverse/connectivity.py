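"""Connectivity (signature-reversal) scoring of drug perturbation profiles.

Each drug's genome-wide differential-expression statistics are ranked
(most up-regulated first) and the disease signature's up and down tag
sets are located in that ranking with a two-sided Kolmogorov–Smirnov
enrichment statistic — the classical connectivity-map construction.
The combined score is

    score = (ES_up - ES_down) / 2          if sign(ES_up) != sign(ES_down)
    score = 0                              otherwise,

bounded in [-1, 1]. A negative score means the drug pushes disease-up
genes down and disease-down genes up, i.e. reverses the signature; the
same-sign rule produces the structural zeros typical of connectivity
screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DisjointSignatureError, DuplicateGeneError, NonNumericValueError
from .signature import DiseaseSignature

ConnectivityClass = Literal["negative", "zero", "positive"]

#: Scores within this tolerance of 0 are classified "zero". The zeros the
#: same-sign rule produces are exact, so the tolerance only guards float noise.
ZERO_TOL = 1e-12


@dataclass
class PerturbationProfile:
    """One drug's gene ranking by differential-expression statistic.

    ``ranked_genes`` is ordered by descending statistic, ties broken by
    lexical gene id, so the ranking is deterministic.
    """

    drug_id: str
    ranked_genes: list[str]
    stats: dict[str, float]

    @classmethod
    def from_stats(cls, drug_id: str, stats: dict[str, float]) -> "PerturbationProfile":
        if len(stats) == 0:
            raise ValueError(f"profile {drug_id!r} has no genes")
        vals = np.fromiter(stats.values(), dtype=float, count=len(stats))
        if not np.isfinite(vals).all():
            raise NonNumericValueError(f"profile {drug_id!r} has non-finite statistics")
        ranked = sorted(stats, key=lambda g: (-stats[g], g))
        return cls(drug_id=drug_id, ranked_genes=ranked, stats=dict(stats))

    def __post_init__(self) -> None:
        if len(set(self.ranked_genes)) != len(self.ranked_genes):
            raise DuplicateGeneError(f"profile {self.drug_id!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.ranked_genes)


@dataclass(frozen=True)
class ConnectivityRecord:
    drug_id: str
    es_up: float
    es_down: float
    score: float
    cls: ConnectivityClass
    n_matched_up: int
    n_matched_down: int


@dataclass
class LibraryResult:
    """Scored library: records sorted ascending (most-reversing first)."""

    records: list[ConnectivityRecord]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_negative(self) -> int:
        return sum(r.cls == "negative" for r in self.records)

    @property
    def n_zero(self) -> int:
        return sum(r.cls == "zero" for r in self.records)

    @property
    def n_positive(self) -> int:
        return sum(r.cls == "positive" for r in self.records)

    def class_of(self) -> dict[str, ConnectivityClass]:
        return {r.drug_id: r.cls for r in self.records}


def ks_enrichment(tag_positions: Sequence[int], n: int) -> float:
    """Two-sided KS enrichment of a tag set within a ranking of length n.

    ``tag_positions`` are the strictly increasing 1-based ranks of the t
    tag genes. With V(j) the rank of the j-th tag,

        a  = max_j [ j/t - V(j)/n ]
        b  = max_j [ V(j)/n - (j-1)/t ]
        ES = a if a >= b else -b

    ES > 0 iff the tags concentrate toward the top of the ranking.
    """
    pos = np.asarray(tag_positions, dtype=float)
    t = pos.size
    if t == 0:
        raise ValueError("empty tag set")
    if t > n:
        raise ValueError(f"more tags ({t}) than ranked genes ({n})")
    if pos[0] < 1 or pos[-1] > n or np.any(np.diff(pos) <= 0):
        raise ValueError("tag positions must be strictly increasing within [1, n]")
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - pos / n)
    b = np.max(pos / n - (j - 1) / t)
    return float(a if a >= b else -b)


def _tag_positions(profile: PerturbationProfile, genes: Iterable[str]) -> list[int]:
    rank = {g: i + 1 for i, g in enumerate(profile.ranked_genes)}
    return sorted(rank[g] for g in genes if g in rank)


def connectivity_score(
    signature: DiseaseSignature, profile: PerturbationProfile
) -> ConnectivityRecord:
    """Score one drug against the disease signature.

    Signature genes absent from the profile are dropped (counts are
    recorded); if either tag set has no overlap with the profile a
    ``DisjointSignatureError`` is raised.
    """
    up_pos = _tag_positions(profile, signature.up_genes)
    down_pos = _tag_positions(profile, signature.down_genes)
    if not up_pos or not down_pos:
        raise DisjointSignatureError(
            f"disjoint signature: drug {profile.drug_id!r} matched "
            f"{len(up_pos)} up / {len(down_pos)} down tag genes"
        )
    n = len(profile)
    es_up = ks_enrichment(up_pos, n)
    es_down = ks_enrichment(down_pos, n)
    if np.sign(es_up) == np.sign(es_down):
        score = 0.0
    else:
        score = (es_up - es_down) / 2.0
    if abs(score) <= ZERO_TOL:
        cls: ConnectivityClass = "zero"
        score = 0.0
    elif score < 0:
        cls = "negative"
    else:
        cls = "positive"
    return ConnectivityRecord(
        drug_id=profile.drug_id,
        es_up=es_up,
        es_down=es_down,
        score=score,
        cls=cls,
        n_matched_up=len(up_pos),
        n_matched_down=len(down_pos),
    )


def score_library(
    signature: DiseaseSignature, profiles: Sequence[PerturbationProfile]
) -> LibraryResult:
    """Score every profile; sort ascending by score (ties lexical by drug).

    Per-drug errors (e.g. disjoint signature) do not abort the screen:
    the drug is skipped and the reason logged in the result.
    """
    if len(profiles) == 0:
        raise ValueError("empty perturbation library")
    records: list[ConnectivityRecord] = []
    skipped: list[tuple[str, str]] = []
    for profile in profiles:
        try:
            records.append(connectivity_score(signature, profile))
        except DisjointSignatureError as exc:
            skipped.append((profile.drug_id, str(exc)))
    records.sort(key=lambda r: (r.score, r.drug_id))
    return LibraryResult(records=records, skipped=skipped)


@dataclass(frozen=True)
class NullSummary:
    observed: float
    mean: float
    sd: float
    p_empirical: float
    n_perm: int


def permutation_null(
    signature: DiseaseSignature,
    profile: PerturbationProfile,
    n_perm: int = 1000,
    seed: int = 0,
) -> NullSummary:
    """Empirical null for one drug's score under random profile orderings.

    Shuffles the ranking ``n_perm`` times (seeded, reproducible) and
    recomputes the score; the two-sided empirical p uses the add-one
    rule p = (1 + #{|null| >= |observed|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    observed = connectivity_score(signature, profile).score
    n = len(profile)
    n_up = sum(g in profile.stats for g in signature.up_genes)
    n_down = sum(g in profile.stats for g in signature.down_genes)
    rng = np.random.default_rng(seed)
    null_scores = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n) + 1
        up_pos = np.sort(perm[:n_up])
        down_pos = np.sort(perm[n_up : n_up + n_down])
        es_up = ks_enrichment(up_pos, n)
        es_down = ks_enrichment(down_pos, n)
        null_scores[i] = 0.0 if np.sign(es_up) == np.sign(es_down) else (es_up - es_down) / 2.0
    p_emp = (1.0 + np.sum(np.abs(null_scores) >= abs(observed))) / (n_perm + 1.0)
    return NullSummary(
        observed=float(observed),
        mean=float(null_scores.mean()),
        sd=float(null_scores.std(ddof=1)),
        p_empirical=float(p_emp),
        n_perm=n_perm,
    )


def read_perturbation_matrix(path) -> list[PerturbationProfile]:
    """Read a wide TSV: rows drugs (first column ``drug_id``), columns genes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise DuplicateGeneError(f"duplicate drug id in {path}")
    profiles = []
    for drug_id, row in df.iterrows():
        profiles.append(PerturbationProfile.from_stats(str(drug_id), row.astype(float).to_dict()))
    return profiles


def read_perturbation_long(path) -> list[PerturbationProfile]:
    """Read a long TSV with columns drug_id, gene_id, stat."""
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "gene_id": str})
    profiles = []
    for drug_id, sub in df.groupby("drug_id", sort=True):
        stats = dict(zip(sub["gene_id"], sub["stat"].astype(float)))
        if len(stats) != len(sub):
            raise DuplicateGeneError(f"duplicate gene for drug {drug_id!r} in {path}")
        profiles.append(PerturbationProfile.from_stats(str(drug_id), stats))
    return profiles


def write_connectivity(result: LibraryResult, path) -> None:
    df = pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in result.records],
            "es_up": [r.es_up for r in result.records],
            "es_down": [r.es_down for r in result.records],
            "score": [r.score for r in result.records],
            "class": [r.cls for r in result.records],
            "n_matched_up": [r.n_matched_up for r in result.records],
            "n_matched_down": [r.n_matched_down for r in result.records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
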
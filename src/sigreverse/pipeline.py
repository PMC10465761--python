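"""End-to-end orchestration: signature -> connectivity -> filter funnel.

``run_pipeline`` consumes a :class:`PipelineConfig` pointing at the
input files, runs the four stages and writes differential.tsv,
connectivity.tsv, funnel.json, funnel.tsv and candidates.tsv into the
output directory. Outputs are deterministic: identical config and
inputs reproduce identical bytes.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import connectivity as conn
from . import filtering as filt
from . import signature as sig
from .errors import EmptySignatureError

log = logging.getLogger("sigreverse")


@dataclass
class PipelineConfig:
    expression_path: str
    groups_path: str
    perturbation_path: str
    annotations_path: str
    docking_path: str
    out_dir: str = "results"
    fc_min: float = sig.DEFAULT_FC_MIN
    p_max: float = sig.DEFAULT_P_MAX
    p_adjust: bool = False
    log2_transform: bool = False
    perturbation_format: str = "matrix"  # matrix | long
    keep_classes: tuple[str, ...] = ("negative", "zero")
    keep_status: tuple[str, ...] = ("approved", "nutraceutical")
    standards: tuple[filt.StandardReference, ...] = filt.DEFAULT_STANDARDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fc_min > 1:
            raise ValueError("fc_min must exceed 1")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load from YAML/JSON; keyword overrides (CLI flags) win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "standards" in raw and raw["standards"] and not isinstance(
            raw["standards"][0], filt.StandardReference
        ):
            raw["standards"] = tuple(
                filt.StandardReference(s["receptor_id"], s["standard_drug"], float(s["binding_energy"]))
                for s in raw["standards"]
            )
        for key in ("keep_classes", "keep_status"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def echo(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "standards"
        }
        d["standards"] = [
            {"receptor_id": s.receptor_id, "standard_drug": s.standard_drug, "binding_energy": s.binding_energy}
            for s in self.standards
        ]
        return d


def run_pipeline(config: PipelineConfig) -> filt.FunnelReport:
    """Run all stages; returns the funnel report (also written to disk).

    Raises :class:`EmptySignatureError` after writing differential.tsv
    if the screen retains no up or no down genes — the later stages are
    undefined without a two-sided signature.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage 1/4: differential screen (FC > %g, p < %g)", config.fc_min, config.p_max)
    expr = sig.read_expression(config.expression_path, config.groups_path, config.log2_transform)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        records, signature = sig.compute_differential(
            expr, config.fc_min, config.p_max, config.p_adjust
        )
    sig.write_differential(records, out / "differential.tsv")
    log.info("  %d up / %d down signature genes", len(signature.up_genes), len(signature.down_genes))
    if signature.is_empty:
        raise EmptySignatureError(
            "stage 1 (signature): screen produced an empty signature; pipeline stopped"
        )

    log.info("stage 2/4: connectivity scoring")
    reader = (
        conn.read_perturbation_matrix
        if config.perturbation_format == "matrix"
        else conn.read_perturbation_long
    )
    profiles = reader(config.perturbation_path)
    result = conn.score_library(signature, profiles)
    conn.write_connectivity(result, out / "connectivity.tsv")
    log.info(
        "  %d scored: %d negative / %d zero / %d positive (%d skipped)",
        len(result.records), result.n_negative, result.n_zero, result.n_positive, len(result.skipped),
    )

    log.info("stage 3/4: market status + BBB filters")
    annotations = filt.read_annotations(config.annotations_path)
    scored = {r.drug_id for r in result.records}
    selected = filt.select_by_connectivity(result.records, frozenset(config.keep_classes))
    safe = filt.filter_status(selected, annotations, frozenset(config.keep_status))
    bbb = filt.filter_bbb(safe, annotations)
    log.info("  %d selected -> %d safe -> %d BBB permeable", len(selected), len(safe), len(bbb))

    log.info("stage 4/4: docking threshold")
    docking = filt.read_docking(config.docking_path)
    final, per_receptor = filt.select_better_than_standard(
        docking, config.standards, require_all=True, drugs=bbb
    )
    log.info("  %d beat all standards (per receptor: %s)", len(final), per_receptor)

    report = filt.build_funnel_report(
        [
            ("scored", scored),
            ("connectivity", selected),
            ("status", safe),
            ("bbb", bbb),
            ("docking", final),
        ],
        class_of=result.class_of(),
        config={**config.echo(), "per_receptor_better": per_receptor},
    )
    report.to_json(out / "funnel.json")
    report.to_tsv(out / "funnel.tsv")
    _write_candidates(result, docking, final, out / "candidates.tsv")
    return report


def _write_candidates(result, docking, final: set[str], path) -> None:
    energies: dict[str, dict[str, float]] = {}
    for rec in docking:
        energies.setdefault(rec.drug_id, {})[rec.receptor_id] = rec.binding_energy
    rows = []
    for r in result.records:
        if r.drug_id in final:
            row = {"drug_id": r.drug_id, "score": r.score, "class": r.cls}
            row.update({f"energy_{k}": v for k, v in sorted(energies.get(r.drug_id, {}).items())})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.echo(), fh, indent=2, sort_keys=True)
        fh.write("\n")
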
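"""End-to-end orchestration: scan → score → QC → annotate → summarize.

A :class:`RunConfig` names the inputs (sequence, structure or precomputed
ΔΔG table, variant table, domain map) and the scoring settings;
:func:`run_pipeline` executes every stage, writes all tabular outputs, and
records a manifest (config echo, seed, package version, output list, QC
status) sufficient to re-execute an identical run. If the internal control
fails, strict mode aborts the run — the control exists to reject poorly
packed structure models before any downstream interpretation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cohort_stats import (
    domain_regression,
    phenotype_domain_counts,
    severity_percentages,
    summarize_by_domain,
    write_domain_summary,
    write_phenotype_matrix,
    write_regression_summary,
)
from .ddg_engine import SurrogateParams, read_ddg_table, read_pdb_minimal, surrogate_ddg, write_ddg_table
from .sequence_domains import default_myo7a_domain_map, load_domain_map, read_fasta
from .unfolding import (
    SeverityThresholds,
    ddg_to_propensity,
    foldability,
    internal_control,
    write_foldability_table,
    write_propensity_table,
    write_qc_report,
)
from .variants import annotate, filter_missense, read_variant_table, validate_against_sequence, write_annotated_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and input context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    sequence_path: str
    out_dir: str
    ddg_path: str | None = None
    structure_path: str | None = None
    variants_path: str | None = None
    domain_map_path: str | None = None
    scale_s: float = 1.0
    thresholds: SeverityThresholds = field(default_factory=SeverityThresholds)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    qc_mean_tolerance: float = 0.05
    qc_ci_halfwidth_tolerance: float = 0.05
    strict_qc: bool = True
    cohort: str = ""
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on the configured inputs; return the manifest dict.

    Exactly one of ``ddg_path`` (precomputed scan from an external engine)
    or ``structure_path`` (surrogate scan over PDB coordinates) must be set.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(name: str, writer, obj) -> Path:
        path = out_dir / name
        writer(obj, path)
        outputs.append(name)
        return path

    try:
        sequence = read_fasta(config.sequence_path)
    except Exception as exc:
        raise PipelineError("sequence", f"{config.sequence_path}: {exc}") from exc

    if (config.ddg_path is None) == (config.structure_path is None):
        raise PipelineError("scan", "set exactly one of ddg_path or structure_path")
    try:
        if config.ddg_path is not None:
            ddg = read_ddg_table(config.ddg_path, sequence)
        else:
            structure = read_pdb_minimal(config.structure_path)
            params = dataclasses.replace(config.surrogate, seed=config.seed)
            ddg = surrogate_ddg(sequence, structure, params)
            emit("ddg.tsv", write_ddg_table, ddg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("scan", str(exc)) from exc

    prop = ddg_to_propensity(ddg, scale_s=config.scale_s)
    emit("propensity.tsv", write_propensity_table, prop)
    emit("foldability.tsv", write_foldability_table, foldability(prop))

    control = internal_control(
        prop,
        sequence,
        mean_tolerance=config.qc_mean_tolerance,
        ci_halfwidth_tolerance=config.qc_ci_halfwidth_tolerance,
    )
    emit("internal_control.json", write_qc_report, control)
    if not control.passed:
        msg = (
            f"internal control failed: mean={control.mean:.4f}, "
            f"ci95=({control.ci95[0]:.4f}, {control.ci95[1]:.4f})"
        )
        if config.strict_qc:
            raise PipelineError("qc", msg)
        logger.warning("%s (continuing: strict_qc disabled)", msg)

    if config.domain_map_path is not None:
        domain_map = load_domain_map(config.domain_map_path)
    else:
        domain_map = default_myo7a_domain_map()
        if domain_map.protein_length != sequence.length:
            raise PipelineError(
                "domains",
                f"default domain map is for a {domain_map.protein_length}-residue "
                f"protein but the sequence has {sequence.length}; pass a domain map",
            )

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "qc_passed": control.passed,
        "outputs": outputs,
    }

    if config.variants_path is not None:
        try:
            records = read_variant_table(config.variants_path)
        except Exception as exc:
            raise PipelineError("variants", f"{config.variants_path}: {exc}") from exc
        kept, excluded, log = filter_missense(records)
        bad = [r for r in kept if validate_against_sequence(r, sequence) != "ok"]
        if bad:
            raise PipelineError(
                "variants",
                f"{len(bad)} missense record(s) inconsistent with the sequence, "
                f"e.g. {bad[0].raw_change!r}",
            )
        annotated = annotate(kept, prop, ddg, domain_map, config.thresholds)
        emit("annotated_variants.tsv", write_annotated_table, annotated)
        emit(
            "domain_summary.tsv",
            write_domain_summary,
            summarize_by_domain(annotated, domain_map, cohort=config.cohort),
        )
        emit(
            "phenotype_domain_matrix.tsv",
            write_phenotype_matrix,
            phenotype_domain_counts(annotated, domain_map),
        )
        severity = severity_percentages(annotated)
        (out_dir / "severity_summary.json").write_text(
            json.dumps(severity.to_dict(), indent=2) + "\n", encoding="utf-8"
        )
        outputs.append("severity_summary.json")
        rows = summarize_by_domain(annotated, domain_map, cohort=config.cohort)
        if len(rows) >= 3:
            emit(
                "domain_regression.json",
                write_regression_summary,
                domain_regression(rows, cohort=config.cohort),
            )
        manifest["n_variants"] = len(records)
        manifest["n_missense"] = len(kept)
        manifest["exclusions"] = log

    manifest["outputs"] = outputs
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest
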
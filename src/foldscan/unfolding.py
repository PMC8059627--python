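"""Unfolding propensities, foldability, severity classes, and model QC.

The scoring layer of the pipeline. Free-energy changes are mapped to a
dimensionless unfolding propensity ρ ∈ [0, 1] by a logistic transform

    ρ = 1 / (1 + exp(−ΔΔG / s)),    s > 0 (kcal/mol, default 1)

so that a neutral substitution (ΔΔG = 0) sits exactly at ρ = 0.5 and
destabilizing substitutions approach 1. Per-residue foldability is the sum
of the 20 propensities in a row (range 0–20); residues near the maximum are
critical for stability no matter what they mutate to.

Two QC devices accompany the scores. The *internal control* collects the
identity-substitution (wild type → wild type) propensities of a scan: on a
well-packed structure these should form a tight distribution centered on
0.5, and systematic departures reveal poor side-chain rotamers in the
underlying model. The *template quality combiner* reduces per-aspect
structure-quality Z scores to one number with fixed weights
0.145·dihedrals + 0.39·packing1D + 0.465·packing3D.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .ddg_engine import AA_INDEX, DdgMatrix
from .sequence_domains import AMINO_ACIDS, ProteinSequence

__all__ = [
    "PropensityMatrix",
    "FoldabilityProfile",
    "SeverityThresholds",
    "InternalControlReport",
    "TemplateQualityZ",
    "ddg_to_propensity",
    "propensity_to_ddg",
    "foldability",
    "classify_severity",
    "internal_control",
    "combine_quality_zscores",
    "write_propensity_table",
    "write_foldability_table",
]

QUALITY_WEIGHTS = {"dihedrals": 0.145, "packing1d": 0.39, "packing3d": 0.465}


@dataclass
class PropensityMatrix:
    """L×20 unfolding propensities in [0, 1]; column order ``ACDEFGHIKLMNPQRSTVWY``."""

    protein_id: str
    wild_type: str
    values: np.ndarray
    scale_s: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(AMINO_ACIDS):
            raise ValueError(f"expected L×20 matrix, got shape {self.values.shape}")
        if self.values.shape[0] != len(self.wild_type):
            raise ValueError("row count does not match wild-type length")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("propensities outside [0, 1]")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def lookup(self, pos: int, aa: str) -> float:
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside [1, {self.length}]")
        return float(self.values[pos - 1, AA_INDEX[aa]])

    def identity_values(self) -> np.ndarray:
        cols = np.fromiter((AA_INDEX[a] for a in self.wild_type), dtype=int)
        return self.values[np.arange(self.length), cols]


@dataclass
class FoldabilityProfile:
    """Per-residue foldability F_i ∈ [0, 20]."""

    protein_id: str
    wild_type: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 20):
            raise ValueError("foldability outside [0, 20]")


@dataclass(frozen=True)
class SeverityThresholds:
    """Bin edges for the four severity categories plus the high-destabilizing flag.

    Categories partition [0, 1] with half-open bins:
    stabilizing ρ ≤ 0.3 < weak ≤ 0.6 < moderate ≤ 0.8 < severe; the
    high-destabilizing flag is the strict rule ρ > 0.9. Edges are
    configurable; 0.9 is the only edge fixed by convention.
    """

    stabilizing_max: float = 0.3
    weak_max: float = 0.6
    moderate_max: float = 0.8
    high_destabilizing_min: float = 0.9

    def __post_init__(self) -> None:
        edges = (
            self.stabilizing_max,
            self.weak_max,
            self.moderate_max,
            self.high_destabilizing_min,
        )
        if not (0 < edges[0] < edges[1] < edges[2] < edges[3] < 1):
            raise ValueError(f"thresholds must satisfy 0 < s < w < m < h < 1, got {edges}")


CATEGORIES = ("stabilizing", "weak", "moderate", "severe")


@dataclass
class InternalControlReport:
    """Statistics of the identity-substitution propensities of one scan."""

    n: int
    mean: float
    sd: float
    ci95: tuple[float, float]
    p_value: float | None
    p_value_vs_half: float | None
    passed: bool
    mean_tolerance: float = 0.05
    ci_halfwidth_tolerance: float = 0.05

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p_value": self.p_value,
            "p_value_vs_half": self.p_value_vs_half,
            "passed": self.passed,
            "mean_tolerance": self.mean_tolerance,
            "ci_halfwidth_tolerance": self.ci_halfwidth_tolerance,
        }


@dataclass(frozen=True)
class TemplateQualityZ:
    dihedrals: float
    packing1d: float
    packing3d: float

    @property
    def overall(self) -> float:
        return combine_quality_zscores(self.dihedrals, self.packing1d, self.packing3d)


def ddg_to_propensity(ddg: DdgMatrix, scale_s: float = 1.0) -> PropensityMatrix:
    """Logistic map ΔΔG → ρ = 1/(1 + exp(−ΔΔG/s)), elementwise.

    Strictly increasing in ΔΔG with ρ(0) = 0.5 exactly; ``scale_s`` (kcal/mol)
    sets how sharply the propensity saturates.
    """
    if scale_s <= 0:
        raise ValueError("scale_s must be positive")
    values = 1.0 / (1.0 + np.exp(-ddg.values / scale_s))
    return PropensityMatrix(
        protein_id=ddg.protein_id,
        wild_type=ddg.wild_type,
        values=values,
        scale_s=scale_s,
    )


def propensity_to_ddg(rho: np.ndarray | float, scale_s: float = 1.0) -> np.ndarray | float:
    """Closed-form inverse of :func:`ddg_to_propensity`: ΔΔG = s·log(ρ/(1−ρ))."""
    rho = np.asarray(rho, dtype=float)
    out = scale_s * np.log(rho / (1.0 - rho))
    return float(out) if out.ndim == 0 else out


def foldability(prop: PropensityMatrix) -> FoldabilityProfile:
    """Row sum of all 20 propensities (identity column included), F_i ∈ [0, 20]."""
    return FoldabilityProfile(
        protein_id=prop.protein_id,
        wild_type=prop.wild_type,
        values=prop.values.sum(axis=1),
    )


def classify_severity(
    rho: float, thresholds: SeverityThresholds = SeverityThresholds()
) -> tuple[str, bool]:
    """Severity category of one propensity plus the high-destabilizing flag.

    Bins are half-open on the left so every ρ ∈ [0, 1] lands in exactly one
    category; the flag uses the strict rule ρ > high_destabilizing_min.
    """
    if not 0 <= rho <= 1:
        raise ValueError(f"propensity {rho} outside [0, 1]")
    if rho <= thresholds.stabilizing_max:
        cat = "stabilizing"
    elif rho <= thresholds.weak_max:
        cat = "weak"
    elif rho <= thresholds.moderate_max:
        cat = "moderate"
    else:
        cat = "severe"
    return cat, rho > thresholds.high_destabilizing_min


def internal_control(
    prop: PropensityMatrix,
    sequence: ProteinSequence | None = None,
    mean_tolerance: float = 0.05,
    ci_halfwidth_tolerance: float = 0.05,
) -> InternalControlReport:
    """QC over the identity-substitution propensities of a scan.

    Reports the mean, sample SD, two-sided 95% t-interval, and one-sample
    t-test p-values (against 0, and against the expected center 0.5). The
    control passes when |mean − 0.5| ≤ ``mean_tolerance`` and the CI
    half-width is ≤ ``ci_halfwidth_tolerance``. A zero-variance sample (the
    noise-free surrogate) degenerates to a point interval at the mean with
    p-values reported as None.
    """
    if sequence is not None and prop.wild_type != sequence.residues:
        raise ValueError("propensity matrix wild type does not match sequence")
    ident = prop.identity_values()
    n = ident.size
    mean = float(ident.mean())
    sd = float(ident.std(ddof=1)) if n > 1 else 0.0
    if sd > 0:
        sem = sd / math.sqrt(n)
        half = float(stats.t.ppf(0.975, n - 1)) * sem
        ci = (mean - half, mean + half)
        p0 = float(stats.ttest_1samp(ident, 0.0).pvalue)
        p_half = float(stats.ttest_1samp(ident, 0.5).pvalue)
        passed = abs(mean - 0.5) <= mean_tolerance and half <= ci_halfwidth_tolerance
    else:
        ci = (mean, mean)
        p0 = p_half = None
        passed = abs(mean - 0.5) <= mean_tolerance
    return InternalControlReport(
        n=n,
        mean=mean,
        sd=sd,
        ci95=ci,
        p_value=p0,
        p_value_vs_half=p_half,
        passed=passed,
        mean_tolerance=mean_tolerance,
        ci_halfwidth_tolerance=ci_halfwidth_tolerance,
    )


def combine_quality_zscores(dihedrals: float, packing1d: float, packing3d: float) -> float:
    """Weighted overall structure-quality Z score.

    Overall = 0.145·dihedrals + 0.39·packing1D + 0.465·packing3D; the weights
    sum to 1 so equal inputs pass through unchanged.
    """
    for name, v in (("dihedrals", dihedrals), ("packing1d", packing1d), ("packing3d", packing3d)):
        if not math.isfinite(v):
            raise ValueError(f"{name} Z score is not finite")
    w = QUALITY_WEIGHTS
    return w["dihedrals"] * dihedrals + w["packing1d"] * packing1d + w["packing3d"] * packing3d


def write_propensity_table(prop: PropensityMatrix, path: str | Path) -> None:
    """TSV writer, dialect ``pos wt A..Y`` (6 significant digits)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pos", "wt", *AMINO_ACIDS])
        for i in range(prop.length):
            writer.writerow(
                [i + 1, prop.wild_type[i], *(f"{v:.6g}" for v in prop.values[i])]
            )


def write_foldability_table(profile: FoldabilityProfile, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pos", "wt", "foldability"])
        for i, v in enumerate(profile.values):
            writer.writerow([i + 1, profile.wild_type[i], f"{v:.6g}"])


def write_qc_report(report: InternalControlReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8")
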
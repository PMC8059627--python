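"""Disease variant tables: parsing, filtering, and annotation.

Consumes HGMD/ClinVar-style exports — one protein-level change (HGVS p.
notation, one- or three-letter) plus a free-text phenotype per row — and
produces annotated records carrying domain, ΔΔG, unfolding propensity, and
severity. Only protein-level notation is supported: every analysis here is
at the protein level, so genomic/cDNA (g., c.) descriptions are out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .ddg_engine import DdgMatrix
from .sequence_domains import AMINO_ACIDS, DomainMap, ProteinSequence, assign_domain
from .unfolding import PropensityMatrix, SeverityThresholds, classify_severity

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "AnnotatedVariant",
    "parse_protein_change",
    "format_protein_change",
    "filter_missense",
    "validate_against_sequence",
    "normalize_phenotype",
    "annotate",
    "read_variant_table",
    "write_annotated_table",
]

STOP = "*"

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": STOP, "Sec": "U",
}

CONSEQUENCES = ("missense", "termination", "indel", "synonymous", "unparsed")


@dataclass(frozen=True)
class VariantRecord:
    """One reported protein change, parsed but not yet annotated."""

    raw_change: str
    wt_aa: str | None
    pos: int | None
    mut_aa: str | None
    consequence: str
    phenotype_raw: str = ""
    phenotype: str = ""
    source: str = "other"
    duplicate: bool = False


@dataclass(frozen=True)
class AnnotatedVariant:
    """A missense record with domain, energetics, and severity attached."""

    raw_change: str
    wt_aa: str
    pos: int
    mut_aa: str
    consequence: str
    phenotype_raw: str
    phenotype: str
    source: str
    domain: str
    ddg: float
    propensity: float
    category: str
    high_destabilizing: bool


_INDEL_RE = re.compile(r"del|ins|dup|fs", re.IGNORECASE)
_ONE_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z*])$")
_THREE_RE = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|\*)$")


def parse_protein_change(text: str) -> tuple[str | None, int | None, str | None, str]:
    """Parse an HGVS-style protein change into (wt, pos, mut, consequence).

    Total: unparseable input yields ``(None, None, None, "unparsed")``.
    Accepts one-letter ("T165M"), optionally "p."-prefixed, and three-letter
    ("p.Thr165Met") forms. Stop spellings X, * and Ter give ``termination``
    (mut canonicalized to "*"); del/ins/dup/fs substrings give ``indel``;
    wt == mut gives ``synonymous``.
    """
    s = str(text).strip()
    if _INDEL_RE.search(s):
        m = re.match(r"^(?:p\.)?(?:([A-Z][a-z]{2})|([A-Z]))(\d+)", s)
        wt = None
        pos = None
        if m:
            wt = _THREE_TO_ONE.get(m.group(1)) if m.group(1) else m.group(2)
            pos = int(m.group(3))
        return wt, pos, None, "indel"
    m = _ONE_RE.match(s)
    if m:
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        if mut == "X":  # HGMD-style stop
            mut = STOP
        if wt not in AMINO_ACIDS:
            return None, None, None, "unparsed"
        if mut == STOP:
            return wt, pos, STOP, "termination"
        if mut not in AMINO_ACIDS:
            return None, None, None, "unparsed"
        return wt, pos, mut, "synonymous" if wt == mut else "missense"
    m = _THREE_RE.match(s)
    if m:
        wt = _THREE_TO_ONE.get(m.group(1))
        mut = STOP if m.group(3) == "*" else _THREE_TO_ONE.get(m.group(3))
        pos = int(m.group(2))
        if wt not in AMINO_ACIDS or wt is None:
            return None, None, None, "unparsed"
        if mut == STOP:
            return wt, pos, STOP, "termination"
        if mut is None or mut not in AMINO_ACIDS:
            return None, None, None, "unparsed"
        return wt, pos, mut, "synonymous" if wt == mut else "missense"
    return None, None, None, "unparsed"


def format_protein_change(wt_aa: str, pos: int, mut_aa: str) -> str:
    """Canonical one-letter form, e.g. ``p.T165M``."""
    return f"p.{wt_aa}{pos}{mut_aa}"


def make_record(
    raw_change: str,
    phenotype_raw: str = "",
    source: str = "other",
) -> VariantRecord:
    wt, pos, mut, consequence = parse_protein_change(raw_change)
    return VariantRecord(
        raw_change=raw_change,
        wt_aa=wt,
        pos=pos,
        mut_aa=mut,
        consequence=consequence,
        phenotype_raw=phenotype_raw,
        phenotype=normalize_phenotype(phenotype_raw),
        source=source,
    )


def filter_missense(
    records: list[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord], dict[str, int]]:
    """Keep missense records; group the rest by exclusion reason.

    Returns ``(kept, excluded, exclusion_log)`` where the log maps each
    non-missense consequence (termination, indel, synonymous, unparsed) to
    its count. |kept| + |excluded| == |records|.
    """
    kept: list[VariantRecord] = []
    excluded: list[VariantRecord] = []
    log: dict[str, int] = {}
    for rec in records:
        if rec.consequence == "missense":
            kept.append(rec)
        else:
            excluded.append(rec)
            log[rec.consequence] = log.get(rec.consequence, 0) + 1
    return kept, excluded, log


def validate_against_sequence(record: VariantRecord, sequence: ProteinSequence) -> str:
    """``ok``, ``wt_mismatch``, or ``out_of_range`` for a parsed record."""
    if record.pos is None or record.wt_aa is None:
        raise ValueError(f"record {record.raw_change!r} is not parsed")
    if not 1 <= record.pos <= sequence.length:
        return "out_of_range"
    if sequence[record.pos] != record.wt_aa:
        return "wt_mismatch"
    return "ok"


# Canonical phenotype vocabulary. Keys are lower-cased, punctuation-stripped
# input labels as they appear in HGMD/ClinVar exports for MYO7A disease.
PHENOTYPE_CATEGORIES = (
    "deafness",
    "hearing loss",
    "USH (unspecified)",
    "USH1",
    "USH1B",
    "USH2",
    "USH3",
    "LCA",
    "RP",
    "retinal dystrophy",
    "keloid",
    "melanoma",
    "MYO7A-related disorder",
    "amyloidosis",
    "inborn genetic disease",
    "pigmentary retinopathy",
    "not provided",
    "other",
)

_PHENOTYPE_MAP: dict[str, str] = {
    "deafness": "deafness",
    "rare genetic deafness": "deafness",
    "nonsyndromic deafness": "deafness",
    "hearing loss": "hearing loss",
    "sensorineural hearing loss": "hearing loss",
    "hearing impairment": "hearing loss",
    "usher syndrome": "USH (unspecified)",
    "us": "USH (unspecified)",
    "ush": "USH (unspecified)",
    "usher syndrome 1": "USH1",
    "usher syndrome type 1": "USH1",
    "us1": "USH1",
    "ush1": "USH1",
    "usher syndrome 1b": "USH1B",
    "usher syndrome type 1b": "USH1B",
    "us1b": "USH1B",
    "ush1b": "USH1B",
    "usher syndrome 2": "USH2",
    "usher syndrome type 2": "USH2",
    "us2": "USH2",
    "ush2": "USH2",
    "usher syndrome 3": "USH3",
    "usher syndrome type 3": "USH3",
    "us3": "USH3",
    "ush3": "USH3",
    "leber congenital amaurosis": "LCA",
    "lca": "LCA",
    "retinitis pigmentosa": "RP",
    "rp": "RP",
    "retinal dystrophy": "retinal dystrophy",
    "keloid": "keloid",
    "keloid formation": "keloid",
    "melanoma": "melanoma",
    "malignant melanoma": "melanoma",
    "myo7a-related disorder": "MYO7A-related disorder",
    "myo7a-related disorders": "MYO7A-related disorder",
    "amyloidosis": "amyloidosis",
    "inborn genetic disease": "inborn genetic disease",
    "inborn genetic diseases": "inborn genetic disease",
    "pigmentary retinopathy": "pigmentary retinopathy",
    "visual and hearing impairment": "other",
    "not provided": "not provided",
    "not specified": "not provided",
    "": "not provided",
}


def normalize_phenotype(label: str) -> str:
    """Map a free-text phenotype label onto the canonical category set.

    Case-insensitive dictionary lookup; unknown labels map to ``other`` with
    a logged warning.
    """
    key = str(label).strip().lower().rstrip(".")
    if key in _PHENOTYPE_MAP:
        return _PHENOTYPE_MAP[key]
    if key in {c.lower() for c in PHENOTYPE_CATEGORIES}:
        return next(c for c in PHENOTYPE_CATEGORIES if c.lower() == key)
    logger.warning("unknown phenotype label %r mapped to 'other'", label)
    return "other"


def annotate(
    records: list[VariantRecord],
    prop: PropensityMatrix,
    ddg: DdgMatrix,
    domain_map: DomainMap,
    thresholds: SeverityThresholds = SeverityThresholds(),
) -> list[AnnotatedVariant]:
    """Attach domain, ΔΔG, propensity, and severity to missense records.

    Records must be parsed missense changes within the matrix range; the
    record count is preserved.
    """
    out: list[AnnotatedVariant] = []
    for rec in records:
        if rec.consequence != "missense" or rec.pos is None:
            raise ValueError(
                f"cannot annotate non-missense record {rec.raw_change!r} "
                f"({rec.consequence})"
            )
        rho = prop.lookup(rec.pos, rec.mut_aa)
        category, high = classify_severity(rho, thresholds)
        out.append(
            AnnotatedVariant(
                raw_change=rec.raw_change,
                wt_aa=rec.wt_aa,
                pos=rec.pos,
                mut_aa=rec.mut_aa,
                consequence=rec.consequence,
                phenotype_raw=rec.phenotype_raw,
                phenotype=rec.phenotype,
                source=rec.source,
                domain=assign_domain(rec.pos, domain_map),
                ddg=ddg.lookup(rec.pos, rec.mut_aa),
                propensity=rho,
                category=category,
                high_destabilizing=high,
            )
        )
    return out


def read_variant_table(path: str | Path, source: str = "other") -> list[VariantRecord]:
    """Read a TSV/CSV with columns ``protein_change`` and ``phenotype``.

    The delimiter is sniffed from the extension (.csv → comma, else tab). A
    ``source`` column overrides the argument. Duplicate (change, phenotype)
    pairs are kept but flagged.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    if "protein_change" not in df.columns:
        raise ValueError(f"{path}: missing required column 'protein_change'")
    records: list[VariantRecord] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        rec = make_record(
            raw_change=row["protein_change"],
            phenotype_raw=row.get("phenotype", ""),
            source=row.get("source", source) or source,
        )
        key = (rec.raw_change, rec.phenotype_raw)
        if key in seen:
            rec = replace(rec, duplicate=True)
        seen.add(key)
        records.append(rec)
    return records


ANNOTATED_COLUMNS = [
    "protein_change",
    "pos",
    "wt",
    "mut",
    "domain",
    "ddg",
    "propensity",
    "category",
    "high_destabilizing",
    "phenotype",
    "source",
]


def annotated_frame(annotated: list[AnnotatedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_change": a.raw_change,
                "pos": a.pos,
                "wt": a.wt_aa,
                "mut": a.mut_aa,
                "domain": a.domain,
                "ddg": a.ddg,
                "propensity": a.propensity,
                "category": a.category,
                "high_destabilizing": a.high_destabilizing,
                "phenotype": a.phenotype,
                "source": a.source,
            }
            for a in annotated
        ],
        columns=ANNOTATED_COLUMNS,
    )


def write_annotated_table(annotated: list[AnnotatedVariant], path: str | Path) -> None:
    annotated_frame(annotated).to_csv(path, sep="\t", index=False, float_format="%.6g")
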
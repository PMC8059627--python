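"""Protein sequences and domain architecture.

Coordinates throughout are 1-based and inclusive on both ends, matching
UniProt feature tables. A :class:`DomainMap` is an ordered set of named
residue ranges; ranges may nest (a region with a ``parent``) and residue
assignment is innermost-wins, so a motif inside a domain shadows the domain
("Motor domain (excluding ATP-binding region)" semantics). The map for human
myosin VIIa (MYO7A, UniProt Q13402, 2,215 aa) ships as a versioned config
file and is exposed via :func:`default_myo7a_domain_map`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ProteinSequence",
    "DomainRegion",
    "DomainMap",
    "DomainMapError",
    "read_fasta",
    "load_domain_map",
    "default_myo7a_domain_map",
    "assign_domain",
]

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

UNASSIGNED = "unassigned"


class DomainMapError(ValueError):
    """Raised for invalid domain-map configs (bad ranges, overlaps, orphan parents)."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence restricted to the 20 canonical residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(AMINO_ACIDS)
        if not self.residues:
            raise ValueError("empty sequence")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-canonical residue(s): "
                f"{''.join(sorted(bad))!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside [1, {len(self.residues)}]")
        return self.residues[pos - 1]


@dataclass(frozen=True)
class DomainRegion:
    """A named residue range, optionally nested inside a parent region."""

    name: str
    start: int
    end: int
    parent: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DomainMapError(
                f"region {self.name!r}: invalid range {self.start}-{self.end}"
            )

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class DomainMap:
    """Ordered collection of domain regions over a protein of known length."""

    regions: list[DomainRegion]
    protein_length: int
    protein_id: str = ""
    version: int | None = None
    _by_name: dict[str, DomainRegion] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {}
        for r in self.regions:
            if r.name in self._by_name:
                raise DomainMapError(f"duplicate region name {r.name!r}")
            self._by_name[r.name] = r
        for r in self.regions:
            if r.end > self.protein_length:
                raise DomainMapError(
                    f"region {r.name!r} ends at {r.end} beyond protein length "
                    f"{self.protein_length}"
                )
            if r.parent is not None:
                p = self._by_name.get(r.parent)
                if p is None:
                    raise DomainMapError(
                        f"region {r.name!r} names unknown parent {r.parent!r}"
                    )
                if not (p.start <= r.start and r.end <= p.end):
                    raise DomainMapError(
                        f"region {r.name!r} ({r.start}-{r.end}) not contained in "
                        f"parent {p.name!r} ({p.start}-{p.end})"
                    )
        self._check_sibling_overlap()

    def _check_sibling_overlap(self) -> None:
        from collections import defaultdict

        sibs: dict[str | None, list[DomainRegion]] = defaultdict(list)
        for r in self.regions:
            sibs[r.parent].append(r)
        for group in sibs.values():
            ordered = sorted(group, key=lambda r: r.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start <= a.end:
                    raise DomainMapError(
                        f"sibling regions {a.name!r} and {b.name!r} overlap "
                        f"({a.start}-{a.end} vs {b.start}-{b.end})"
                    )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterable[DomainRegion]:
        return iter(self.regions)

    def region(self, name: str) -> DomainRegion:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "protein_length": self.protein_length,
            "version": self.version,
            "regions": [
                {"name": r.name, "start": r.start, "end": r.end, "parent": r.parent}
                for r in self.regions
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DomainMap":
        try:
            length = int(data["protein_length"])
            raw = data["regions"]
        except KeyError as exc:
            raise DomainMapError(f"domain map config missing key: {exc}") from exc
        regions = []
        for i, entry in enumerate(raw):
            try:
                regions.append(
                    DomainRegion(
                        name=str(entry["name"]),
                        start=int(entry["start"]),
                        end=int(entry["end"]),
                        parent=entry.get("parent"),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise DomainMapError(f"regions[{i}]: {exc}") from exc
        return cls(
            regions=regions,
            protein_length=length,
            protein_id=str(data.get("protein_id", "")),
            version=data.get("version"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )


def read_fasta(path: str | Path) -> ProteinSequence:
    """Read the first record of a FASTA file as a :class:`ProteinSequence`.

    The record id is the first whitespace-delimited token of the header.
    Raises ``ValueError`` on an empty file or on residues outside the 20
    canonical one-letter codes (gaps, X, U, ...).
    """
    records = SeqIO.parse(str(path), "fasta")
    first = next(iter(records), None)
    if first is None:
        raise ValueError(f"no FASTA records in {path}")
    return ProteinSequence(id=first.id, residues=str(first.seq).upper())


def write_fasta(seq: ProteinSequence, path: str | Path, width: int = 60) -> None:
    lines = [f">{seq.id}"]
    lines += [seq.residues[i : i + width] for i in range(0, len(seq), width)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_domain_map(path: str | Path) -> DomainMap:
    """Load and validate a JSON domain-map config."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DomainMapError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
    return DomainMap.from_dict(data)


def default_myo7a_domain_map() -> DomainMap:
    """The bundled human MYO7A domain map (15 regions, protein length 2,215).

    Motor domain 65-741 with nested ATP-binding motif 158-165 and
    actin-binding site 632-639; five IQ calmodulin-binding motifs; coiled
    coil 858-1016 with nested single α-helix 858-935; then the tail:
    MyTH4-FERM-SH3-MyTH4-FERM.
    """
    ref = resources.files("foldscan.data") / "myo7a_domains.json"
    return DomainMap.from_dict(json.loads(ref.read_text(encoding="utf-8")))


def assign_domain(pos: int, domain_map: DomainMap) -> str:
    """Name of the innermost region containing 1-based ``pos``.

    Positions inside a parent but outside all of its children report the
    parent; positions covered by no region report ``"unassigned"``.
    """
    if not 1 <= pos <= domain_map.protein_length:
        raise ValueError(
            f"position {pos} outside [1, {domain_map.protein_length}]"
        )
    best: DomainRegion | None = None
    best_depth = -1
    for r in domain_map.regions:
        if pos in r:
            depth = 0
            p = r.parent
            while p is not None:
                depth += 1
                p = domain_map.region(p).parent
            if depth > best_depth:
                best, best_depth = r, depth
    return best.name if best is not None else UNASSIGNED
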
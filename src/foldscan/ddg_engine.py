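"""ΔΔG matrix I/O and a transparent surrogate stability engine.

A saturating in-silico mutagenesis scan produces an L×20 matrix of unfolding
free-energy changes ΔΔG (kcal/mol, mutant minus wild type; positive values
destabilize). Production scans come from external stability calculators and
enter through :func:`read_ddg_table`. For self-contained runs this module
also provides :func:`surrogate_ddg`, a deliberately simple, deterministic
scoring function over coarse structural burial:

    ΔΔG(i, b) = b_i · ( w_h·(H(wt_i) − H(b)) + w_v·|V(b) − V(wt_i)|/100 )
                + w_p·[b == P and wt_i ≠ P] + ε_i·[b == wt_i]

where b_i is the contact burial of residue i, H the Kyte–Doolittle
hydropathy, V the Zamyatnin residue volume (Å³) and ε_i optional Gaussian
rotamer noise on the identity (self-substitution) diagonal. The surrogate
makes no claim to match any published per-mutation energies; it exists so
the downstream propensity/foldability/annotation pipeline is runnable and
testable without an external engine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_domains import AMINO_ACIDS, ProteinSequence

__all__ = [
    "DdgMatrix",
    "StructureModel",
    "StructureResidue",
    "SurrogateParams",
    "KD_HYDROPATHY",
    "RESIDUE_VOLUME",
    "read_ddg_table",
    "write_ddg_table",
    "read_pdb_minimal",
    "contact_burial",
    "burial_profile",
    "surrogate_ddg",
]

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _load_constant_table(name: str) -> dict[str, float]:
    ref = resources.files("foldscan.data") / name
    out: dict[str, float] = {}
    for line in ref.read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        out[aa] = float(value)
    if set(out) != set(AMINO_ACIDS):
        raise RuntimeError(f"constant table {name} does not cover the 20 amino acids")
    return out


#: Kyte–Doolittle hydropathy index (dimensionless).
KD_HYDROPATHY: dict[str, float] = _load_constant_table("kyte_doolittle.tsv")
#: Mean residue volumes in Å³ (Zamyatnin 1972).
RESIDUE_VOLUME: dict[str, float] = _load_constant_table("residue_volumes.tsv")


@dataclass
class DdgMatrix:
    """L×20 grid of free-energy changes from a saturating mutation scan.

    Rows follow 1-based residue position; columns follow the fixed
    alphabetical one-letter amino-acid order ``ACDEFGHIKLMNPQRSTVWY``.
    ``values[i-1, AA_INDEX[wt[i-1]]]`` is the identity-substitution entry.
    """

    protein_id: str
    wild_type: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(AMINO_ACIDS):
            raise ValueError(f"expected L×20 matrix, got shape {self.values.shape}")
        if self.values.shape[0] != len(self.wild_type):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.wild_type)} wild-type residues"
            )
        bad = set(self.wild_type) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical wild-type residues: {''.join(sorted(bad))!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ΔΔG matrix contains non-finite entries")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def lookup(self, pos: int, aa: str) -> float:
        """ΔΔG for substituting residue ``pos`` (1-based) by ``aa``."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside [1, {self.length}]")
        return float(self.values[pos - 1, AA_INDEX[aa]])

    def identity_values(self) -> np.ndarray:
        """The L identity-substitution (wild type → wild type) entries."""
        cols = np.fromiter((AA_INDEX[a] for a in self.wild_type), dtype=int)
        return self.values[np.arange(self.length), cols]


@dataclass(frozen=True)
class StructureResidue:
    chain: str
    number: int
    aa: str
    coord: tuple[float, float, float]


@dataclass
class StructureModel:
    """Ordered one-point-per-residue model (representative atom = Cβ, Cα for Gly)."""

    residues: list[StructureResidue]

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        for r in self.residues:
            if r.chain in last and r.number <= last[r.chain]:
                raise ValueError(
                    f"residue numbers not strictly increasing in chain {r.chain!r}"
                )
            last[r.chain] = r.number
            if not all(np.isfinite(c) for c in r.coord):
                raise ValueError(f"non-finite coordinate at {r.chain}/{r.number}")

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        return np.array([r.coord for r in self.residues], dtype=float)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass(frozen=True)
class SurrogateParams:
    """Knobs of the surrogate scoring function.

    contact_radius, Å: neighbour cutoff for burial counting.
    n_max: contact count at which burial saturates at 1.
    w_h: kcal/mol per unit of hydropathy lost on substitution.
    w_v: kcal/mol per 100 Å³ of absolute side-chain volume change.
    w_p: flat penalty (kcal/mol) for introducing a proline.
    identity_noise_sd: SD (kcal/mol) of Gaussian noise on identity entries,
        emulating imperfect side-chain rotamers in a homology model.
    """

    contact_radius: float = 10.0
    n_max: int = 20
    w_h: float = 0.5
    w_v: float = 0.5
    w_p: float = 1.0
    identity_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_radius <= 0:
            raise ValueError("contact_radius must be positive")
        if self.n_max < 1:
            raise ValueError("n_max must be ≥ 1")
        if self.identity_noise_sd < 0:
            raise ValueError("identity_noise_sd must be ≥ 0")


# --------------------------------------------------------------------------
# TSV dialect: header `pos\twt\tA\t...\tY`, one row per residue.

_HEADER = ["pos", "wt", *AMINO_ACIDS]


def read_ddg_table(path: str | Path, sequence: ProteinSequence) -> DdgMatrix:
    """Read a ΔΔG TSV and validate it against ``sequence``.

    Requires exactly one row per residue position 1..L, a ``wt`` column
    matching the sequence, and numeric entries in all 20 amino-acid columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pos": int, "wt": str}, comment="#")
    if list(df.columns) != _HEADER:
        raise ValueError(
            f"{path}: expected header {' '.join(_HEADER)!r}, got {' '.join(df.columns)!r}"
        )
    pos = df["pos"].to_numpy()
    dup = pd.Series(pos).duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicated position(s) {sorted(set(pos[dup.to_numpy()]))}")
    expected = set(range(1, sequence.length + 1))
    missing = expected - set(pos.tolist())
    extra = set(pos.tolist()) - expected
    if missing or extra:
        raise ValueError(
            f"{path}: positions do not cover 1..{sequence.length} "
            f"(missing {sorted(missing)[:5]}..., extra {sorted(extra)[:5]}...)"
        )
    df = df.sort_values("pos")
    wt = "".join(df["wt"].tolist())
    if wt != sequence.residues:
        first = next(i for i, (a, b) in enumerate(zip(wt, sequence.residues), 1) if a != b)
        raise ValueError(
            f"{path}: wt column mismatches sequence at position {first} "
            f"({wt[first-1]!r} vs {sequence.residues[first-1]!r})"
        )
    try:
        values = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric ΔΔG cell: {exc}") from exc
    return DdgMatrix(protein_id=sequence.id, wild_type=wt, values=values)


def write_ddg_table(matrix: DdgMatrix, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`read_ddg_table` (6 significant digits)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for i in range(matrix.length):
            writer.writerow(
                [i + 1, matrix.wild_type[i], *(f"{v:.6g}" for v in matrix.values[i])]
            )


# --------------------------------------------------------------------------
# Minimal PDB reading (ATOM records only).

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_pdb_minimal(path: str | Path) -> StructureModel:
    """Read ATOM records of a PDB file into a one-point-per-residue model.

    The representative atom is Cβ, falling back to Cα for glycine or when Cβ
    is absent. Only blank or 'A' alternate-location indicators are used;
    insertion codes are rejected. HETATM records are ignored.
    """
    ca: dict[tuple[str, int], tuple[str, tuple[float, float, float]]] = {}
    cb: dict[tuple[str, int], tuple[str, tuple[float, float, float]]] = {}
    order: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("ATOM"):
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            icode = line[26]
            if icode != " ":
                raise ValueError(
                    f"{path}:{lineno}: insertion code {icode!r} not supported; "
                    "renumber residues first"
                )
            atom = line[12:16].strip()
            if atom not in ("CA", "CB"):
                continue
            resname = line[17:20].strip()
            aa = _THREE_TO_ONE.get(resname)
            if aa is None:
                continue
            chain = line[21]
            try:
                resnum = int(line[22:26])
                coord = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed ATOM fields: {exc}") from exc
            key = (chain, resnum)
            if key not in seen:
                seen.add(key)
                order.append(key)
            target = ca if atom == "CA" else cb
            target.setdefault(key, (aa, coord))
    if not order:
        raise ValueError(f"{path}: no ATOM records")
    residues = []
    for key in order:
        aa, coord = cb.get(key, ca.get(key, (None, None)))  # type: ignore[arg-type]
        if aa is None:
            continue
        residues.append(StructureResidue(chain=key[0], number=key[1], aa=aa, coord=coord))
    return StructureModel(residues=residues)


# --------------------------------------------------------------------------
# Burial and the surrogate scan.


def _neighbor_counts(structure: StructureModel, radius: float) -> np.ndarray:
    """Per-residue count of non-adjacent residues within ``radius`` Å."""
    from scipy.spatial import cKDTree

    xyz = structure.coords()
    n = len(structure)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    counts = np.zeros(n, dtype=int)
    res = structure.residues
    for i, j in pairs:
        # chain-adjacent neighbours are trivially in contact; skip them
        if res[i].chain == res[j].chain and abs(res[i].number - res[j].number) <= 1:
            continue
        counts[i] += 1
        counts[j] += 1
    return counts


def contact_burial(structure: StructureModel, i: int, params: SurrogateParams) -> float:
    """Burial fraction of the i-th residue (1-based index into the model).

    b_i = min(1, N_i / n_max) with N_i the number of representative atoms of
    sequence-non-adjacent residues within ``contact_radius``.
    """
    if not 1 <= i <= len(structure):
        raise ValueError(f"residue index {i} outside [1, {len(structure)}]")
    counts = _neighbor_counts(structure, params.contact_radius)
    return float(min(1.0, counts[i - 1] / params.n_max))


def burial_profile(structure: StructureModel, params: SurrogateParams) -> np.ndarray:
    """Vector of burial fractions for every residue in the model."""
    counts = _neighbor_counts(structure, params.contact_radius)
    return np.minimum(1.0, counts / params.n_max)


def surrogate_ddg(
    sequence: ProteinSequence,
    structure: StructureModel,
    params: SurrogateParams = SurrogateParams(),
) -> DdgMatrix:
    """Score every substitution of ``sequence`` with the surrogate function.

    The structure must carry the same residues in the same order as the
    sequence (chain/renumbering is ignored; only order matters). Burial
    scales the hydropathy and volume terms, so fully exposed positions score
    0 for every non-proline substitution; with ``identity_noise_sd=0`` the
    identity diagonal is exactly 0.
    """
    if len(structure) != sequence.length:
        raise ValueError(
            f"structure has {len(structure)} residues but sequence has {sequence.length}"
        )
    model_seq = structure.sequence()
    if model_seq != sequence.residues:
        first = next(
            i for i, (a, b) in enumerate(zip(model_seq, sequence.residues), 1) if a != b
        )
        raise ValueError(f"structure/sequence letter mismatch at position {first}")

    b = burial_profile(structure, params)
    h = np.array([KD_HYDROPATHY[a] for a in AMINO_ACIDS])
    v = np.array([RESIDUE_VOLUME[a] for a in AMINO_ACIDS])
    h_wt = np.array([KD_HYDROPATHY[a] for a in sequence.residues])
    v_wt = np.array([RESIDUE_VOLUME[a] for a in sequence.residues])

    bracket = params.w_h * (h_wt[:, None] - h[None, :]) + params.w_v * np.abs(
        v[None, :] - v_wt[:, None]
    ) / 100.0
    values = b[:, None] * bracket
    p_col = AA_INDEX["P"]
    values[:, p_col] += params.w_p * (np.array(list(sequence.residues)) != "P")

    wt_cols = np.fromiter((AA_INDEX[a] for a in sequence.residues), dtype=int)
    rows = np.arange(sequence.length)
    values[rows, wt_cols] = 0.0
    if params.identity_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        values[rows, wt_cols] = rng.normal(0.0, params.identity_noise_sd, sequence.length)
    return DdgMatrix(protein_id=sequence.id, wild_type=sequence.residues, values=values)
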
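"""Synthetic inputs for every pipeline stage.

Everything the pipeline consumes can be generated here with controlled
statistical structure and bit-reproducible seeding: protein sequences,
coarse 3D structures (compact self-avoiding virtual-bond walks), ΔΔG
matrices whose destabilization grows with burial and whose identity
(self-substitution) entries scatter near 0, and variant cohorts with exact
per-severity-category counts.

The two cohort fixtures (:func:`hgmd_like_spec`, :func:`clinvar_like_spec`)
mirror the *printed marginal counts* of the published MYO7A HGMD and ClinVar
analyses — total records, exclusions, severity-category counts, phenotype
mix — not the unpublished per-variant lists. They are synthetic look-alikes
for exercising the pipeline, never real HGMD/ClinVar data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddg_engine import DdgMatrix, StructureModel, StructureResidue
from .sequence_domains import AMINO_ACIDS, DomainMap, ProteinSequence
from .unfolding import CATEGORIES, SeverityThresholds
from .variants import VariantRecord, make_record

__all__ = [
    "CohortSpec",
    "random_protein_sequence",
    "simulate_structure",
    "simulate_ddg_matrix",
    "simulate_cohort",
    "positions_for_domain_counts",
    "hgmd_like_spec",
    "clinvar_like_spec",
]

# Distinct sub-streams so adding a generator never perturbs existing fixtures.
_STREAM = {"sequence": 1, "structure": 2, "ddg": 3, "cohort": 4, "positions": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], seed])


def random_protein_sequence(length: int, seed: int, id: str = "synthetic") -> ProteinSequence:
    """Uniform-composition random sequence over the 20 canonical residues."""
    if length < 1:
        raise ValueError("length must be ≥ 1")
    rng = _rng(seed, "sequence")
    letters = rng.choice(list(AMINO_ACIDS), size=length)
    return ProteinSequence(id=id, residues="".join(letters))


def simulate_structure(
    length: int,
    seed: int,
    sequence: ProteinSequence | None = None,
    bond_length: float = 3.8,
    min_separation: float = 3.5,
    tail_fraction: float = 0.15,
) -> StructureModel:
    """Compact self-avoiding random walk on a virtual-bond chain.

    Successive residues sit ``bond_length`` Å apart (the Cα virtual-bond
    distance). Steps are biased toward the origin while outside a core
    radius scaling as L^(1/3), producing a dense globular core; the final
    ``tail_fraction`` of the chain walks outward instead, so the burial
    spectrum spans exposed (b ≈ 0) to saturated (b = 1) positions, as in a
    real single-domain protein with a disordered terminus. Steps closer than
    ``min_separation`` Å to any existing non-adjacent residue are rejected
    (with a bounded number of retries, keeping the best candidate).
    """
    if length < 1:
        raise ValueError("length must be ≥ 1")
    if sequence is not None and sequence.length != length:
        raise ValueError("sequence length does not match requested structure length")
    letters = sequence.residues if sequence is not None else "A" * length
    rng = _rng(seed, "structure")
    coords = np.zeros((length, 3))
    core_radius = 2.4 * length ** (1 / 3)
    n_core = max(1, int(round(length * (1 - tail_fraction))))
    for i in range(1, length):
        prev = coords[i - 1]
        best = None
        best_clearance = -np.inf
        for _ in range(40):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radial = np.linalg.norm(prev)
            if i < n_core:
                if radial > core_radius:
                    direction = direction - 1.5 * prev / radial
                    direction /= np.linalg.norm(direction)
            else:
                # tail: drift outward from the globule
                out = prev / radial if radial > 0 else direction
                direction = direction + 2.0 * out
                direction /= np.linalg.norm(direction)
            cand = prev + bond_length * direction
            if i >= 2:
                clearance = float(np.min(np.linalg.norm(coords[: i - 1] - cand, axis=1)))
            else:
                clearance = np.inf
            if clearance >= min_separation:
                best = cand
                break
            if clearance > best_clearance:
                best, best_clearance = cand, clearance
        coords[i] = best
    residues = [
        StructureResidue(chain="A", number=i + 1, aa=letters[i], coord=tuple(coords[i]))
        for i in range(length)
    ]
    return StructureModel(residues=residues)


def simulate_ddg_matrix(
    sequence: ProteinSequence,
    burial_profile: np.ndarray,
    identity_noise_sd: float = 0.0,
    seed: int = 0,
    slope: float = 2.0,
    noise_sd: float = 1.0,
) -> DdgMatrix:
    """ΔΔG matrix with destabilization growing with burial.

    Non-identity entries draw from Normal(slope·b_i, noise_sd) kcal/mol;
    identity entries draw from Normal(0, identity_noise_sd), emulating the
    rotamer noise a real homology model shows on self-substitutions.
    """
    b = np.asarray(burial_profile, dtype=float)
    if b.shape != (sequence.length,):
        raise ValueError(
            f"burial profile length {b.shape} does not match sequence ({sequence.length})"
        )
    rng = _rng(seed, "ddg")
    values = rng.normal(loc=slope * b[:, None], scale=noise_sd, size=(sequence.length, 20))
    rows = np.arange(sequence.length)
    cols = np.fromiter((AMINO_ACIDS.index(a) for a in sequence.residues), dtype=int)
    if identity_noise_sd > 0:
        values[rows, cols] = rng.normal(0.0, identity_noise_sd, sequence.length)
    else:
        values[rows, cols] = 0.0
    return DdgMatrix(protein_id=sequence.id, wild_type=sequence.residues, values=values)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic variant cohort with exact category counts.

    ``category_counts`` applies to the missense subset
    (n_records − n_termination − n_indel) and must sum to it;
    ``n_high_destabilizing`` is the portion of the severe count drawn above
    the high-destabilizing cut.
    """

    n_records: int
    n_termination: int = 0
    n_indel: int = 0
    category_counts: dict[str, int] = field(default_factory=dict)
    n_high_destabilizing: int = 0
    phenotype_mix: dict[str, float] = field(default_factory=dict)
    source: str = "other"
    seed: int = 0

    @property
    def n_missense(self) -> int:
        return self.n_records - self.n_termination - self.n_indel

    def __post_init__(self) -> None:
        if self.n_records < 0 or self.n_termination < 0 or self.n_indel < 0:
            raise ValueError("counts must be non-negative")
        unknown = set(self.category_counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown severity categories: {sorted(unknown)}")
        total = sum(self.category_counts.values())
        if total != self.n_missense:
            raise ValueError(
                f"category counts sum to {total}, expected "
                f"{self.n_missense} (n_records − n_termination − n_indel)"
            )
        if self.n_high_destabilizing > self.category_counts.get("severe", 0):
            raise ValueError(
                "n_high_destabilizing exceeds the severe count "
                f"({self.n_high_destabilizing} > {self.category_counts.get('severe', 0)})"
            )


def _category_bounds(thresholds: SeverityThresholds) -> dict[str, tuple[float, float]]:
    return {
        "stabilizing": (0.0, thresholds.stabilizing_max),
        "weak": (thresholds.stabilizing_max, thresholds.weak_max),
        "moderate": (thresholds.weak_max, thresholds.moderate_max),
        # severe splits at the high-destabilizing cut; handled separately
        "severe": (thresholds.moderate_max, thresholds.high_destabilizing_min),
    }


def simulate_cohort(
    spec: CohortSpec,
    thresholds: SeverityThresholds = SeverityThresholds(),
    sequence: ProteinSequence | None = None,
    protein_length: int = 2215,
    positions: list[int] | None = None,
) -> pd.DataFrame:
    """Synthetic variant table with per-variant propensities.

    Returns a DataFrame with columns ``protein_change``, ``phenotype``,
    ``source``, ``consequence``, ``propensity`` (NaN on non-missense rows).
    Each missense record draws its propensity uniformly inside its severity
    category's bin (high-destabilizing records from the open interval above
    the cut), so classifying the drawn propensities recovers the spec's
    category counts exactly. Positions draw uniformly over the protein
    unless an explicit ``positions`` list (one per missense record) is given.
    """
    rng = _rng(spec.seed, "cohort")
    if sequence is None:
        sequence = random_protein_sequence(protein_length, spec.seed)
    bounds = _category_bounds(thresholds)

    rhos: list[float] = []
    cats: list[str] = []
    for cat in CATEGORIES:
        k = spec.category_counts.get(cat, 0)
        if cat == "severe":
            k_high = spec.n_high_destabilizing
            lo, hi = bounds[cat]
            rhos += list(rng.uniform(lo, hi, size=k - k_high))
            rhos += list(rng.uniform(thresholds.high_destabilizing_min, 1.0, size=k_high))
            cats += [cat] * k
        else:
            lo, hi = bounds[cat]
            rhos += list(rng.uniform(lo, hi, size=k))
            cats += [cat] * k

    n_missense = spec.n_missense
    if positions is not None:
        if len(positions) != n_missense:
            raise ValueError(
                f"{len(positions)} positions given for {n_missense} missense records"
            )
        pos_arr = np.asarray(positions, dtype=int)
    else:
        pos_arr = rng.integers(1, sequence.length + 1, size=n_missense)

    rows: list[dict] = []
    for pos, rho in zip(pos_arr, rhos):
        wt = sequence[int(pos)]
        mut = wt
        while mut == wt:
            mut = AMINO_ACIDS[rng.integers(0, 20)]
        rows.append(
            {
                "protein_change": f"p.{wt}{pos}{mut}",
                "consequence": "missense",
                "propensity": float(rho),
            }
        )
    for _ in range(spec.n_termination):
        pos = int(rng.integers(1, sequence.length + 1))
        rows.append(
            {
                "protein_change": f"p.{sequence[pos]}{pos}*",
                "consequence": "termination",
                "propensity": np.nan,
            }
        )
    for _ in range(spec.n_indel):
        pos = int(rng.integers(1, sequence.length + 1))
        rows.append(
            {
                "protein_change": f"p.{sequence[pos]}{pos}del",
                "consequence": "indel",
                "propensity": np.nan,
            }
        )

    if spec.phenotype_mix:
        names = list(spec.phenotype_mix)
        probs = np.array([spec.phenotype_mix[n] for n in names], dtype=float)
        probs /= probs.sum()
        phenos = rng.choice(names, size=len(rows), p=probs)
    else:
        phenos = np.array(["not provided"] * len(rows))

    order = rng.permutation(len(rows))
    df = pd.DataFrame(
        [
            {
                **rows[i],
                "phenotype": phenos[i],
                "source": spec.source,
            }
            for i in order
        ],
        columns=["protein_change", "phenotype", "source", "consequence", "propensity"],
    )
    return df


def cohort_records(df: pd.DataFrame) -> list[VariantRecord]:
    """Re-parse a simulated cohort table into variant records."""
    return [
        make_record(row.protein_change, phenotype_raw=row.phenotype, source=row.source)
        for row in df.itertuples()
    ]


def positions_for_domain_counts(
    domain_map: DomainMap,
    counts: dict[str, int],
    seed: int = 0,
    include_children: bool = True,
) -> list[int]:
    """Sample residue positions hitting exact per-region counts.

    ``counts`` maps region names to the number of positions to draw
    uniformly inside each region's range (children of the region included by
    default, so a parent-domain count covers its nested motifs too).
    """
    rng = _rng(seed, "positions")
    out: list[int] = []
    for name, k in counts.items():
        r = domain_map.region(name)
        out += [int(p) for p in rng.integers(r.start, r.end + 1, size=k)]
    return out


def hgmd_like_spec(seed: int = 0) -> CohortSpec:
    """Cohort fixture mirroring the published HGMD MYO7A marginals.

    213 records of which 35 are premature terminations; the 178 missense
    records split severe 93 (77 above the high-destabilizing cut),
    moderate 51, stabilizing 30, weak 4. The phenotype mix follows the
    printed HGMD phenotype counts, used here as proportions.
    """
    return CohortSpec(
        n_records=213,
        n_termination=35,
        n_indel=0,
        category_counts={"severe": 93, "moderate": 51, "stabilizing": 30, "weak": 4},
        n_high_destabilizing=77,
        phenotype_mix={
            "deafness": 19,
            "hearing loss": 29,
            "keloid": 2,
            "LCA": 1,
            "Usher syndrome": 5,
            "Usher syndrome 1": 57,
            "Usher syndrome 1b": 46,
            "Usher syndrome 2": 8,
            "malignant melanoma": 1,
            "Usher syndrome 3": 1,
        },
        source="hgmd-like",
        seed=seed,
    )


def clinvar_like_spec(seed: int = 0) -> CohortSpec:
    """Cohort fixture mirroring the published ClinVar MYO7A marginals.

    530 records of which 2 are indels; the 528 missense records split
    severe 266 (221 above the high-destabilizing cut), moderate 201,
    stabilizing 16, weak 45. The published per-category counts sum to 532
    against a stated 528 total; the weak count absorbs the −4 residual so
    the severe and high-destabilizing fractions match the published
    percentages. Phenotype mix from the printed ClinVar phenotype counts,
    with the large unspecified fraction mapped to "not provided".
    """
    return CohortSpec(
        n_records=530,
        n_termination=0,
        n_indel=2,
        category_counts={"severe": 266, "moderate": 201, "stabilizing": 16, "weak": 45},
        n_high_destabilizing=221,
        phenotype_mix={
            "rare genetic deafness": 51,
            "Usher syndrome": 5,
            "Usher syndrome 1": 97,
            "Usher syndrome 1b": 97,
            "Usher syndrome 2": 2,
            "retinal dystrophy": 16,
            "MYO7A-related disorders": 7,
            "retinitis pigmentosa": 3,
            "amyloidosis": 1,
            "inborn genetic diseases": 1,
            "pigmentary retinopathy": 1,
            "not provided": 207,
        },
        source="clinvar-like",
        seed=seed,
    )
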
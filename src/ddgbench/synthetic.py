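"""Synthetic fixtures: mutation tables, predictions, and toy structures.

Everything here is a pure function of its parameters and seed, so tests and
end-to-end runs are reproducible without any external data.  The mutation
generator draws experimental ΔΔG from a three-component Gaussian mixture
whose components sit at −1.5 / 0 / +1.5 kcal/mol (sd 0.5) so all three
stability classes are populated; the default mixing weights
(0.15 / 0.35 / 0.50) skew destabilizing, the usual shape of point-mutation
stability data.  Predictions are a linear transform of the experimental
value plus Gaussian noise, which gives metrics a known attenuation to
recover.  Toy structures are ideal poly-alanine helices (Cβ side chains)
and a packed pseudo-atom core that realise inter-chain contacts and
buried/exposed residues with known geometry.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import MutationRecord, PredictionRecord
from .structure import Atom, Structure, relative_sasa
from .taxonomy import CANONICAL_AA, CategoryLabel, ValidationError, classify_mutation

__all__ = [
    "SyntheticSpec",
    "pairs_for_label",
    "gen_parent_sequences",
    "gen_parent_structures",
    "gen_mutation_table",
    "gen_predictions",
    "gen_two_chain_helices",
    "gen_packed_core",
]

DDG_MEANS = (-1.5, 0.0, 1.5)   # stabilizing / neutral / destabilizing components
DDG_SD = 0.5
DDG_WEIGHTS = (0.15, 0.35, 0.50)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic mutation table."""

    n_records: int
    category_mix: Mapping[CategoryLabel, float] = field(default_factory=dict)
    ddg_means: tuple[float, float, float] = DDG_MEANS
    ddg_sd: float = DDG_SD
    ddg_weights: tuple[float, float, float] = DDG_WEIGHTS
    prediction_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 1:
            raise ValidationError("n_records must be ≥ 1")
        if not math.isclose(sum(self.ddg_weights), 1.0, abs_tol=1e-9):
            raise ValidationError("ddg_weights must sum to 1")
        total = 0.0
        for label, frac in self.category_mix.items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"fraction for {label} outside [0, 1]: {frac}")
            total += frac
        if total > 1.0 + 1e-9:
            raise ValidationError(f"category_mix fractions sum to {total} > 1")


def pairs_for_label(label: CategoryLabel) -> list[tuple[str, str]]:
    """All ordered (wt, mut) pairs realising a sequence-level category."""
    pairs = [
        (wt, mut)
        for wt, mut in itertools.permutations(sorted(CANONICAL_AA), 2)
        if label in classify_mutation(wt, mut)
    ]
    return pairs


def gen_parent_sequences(
    n_parents: int = 8, length: int = 80, seed: int = 0
) -> dict[str, str]:
    """Random unrelated parent sequences, one per synthetic PDB id.

    Independent uniform sequences sit near 5% pairwise identity, far below
    any dedup threshold, so each parent forms its own cluster.
    """
    rng = np.random.default_rng(seed)
    alphabet = sorted(CANONICAL_AA)
    return {
        f"SY{i:02d}": "".join(alphabet[j] for j in rng.integers(20, size=length))
        for i in range(n_parents)
    }


def gen_mutation_table(
    spec: SyntheticSpec,
    parent_sequences: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Generate records whose category fractions match the requested mix.

    The requested fraction of each category is realised by drawing
    (wt, mut) pairs uniformly from the pairs carrying that label; the
    remaining mass uses uniformly random valid pairs.  Categories that no
    residue pair can realise (Buried, Surface) are a configuration error.
    Each record is placed on a parent sequence at a position whose residue
    equals the wild type, so mutation tables stay consistent with the
    structures of :func:`gen_parent_structures`.
    """
    rng = np.random.default_rng(spec.seed)
    if parent_sequences is None:
        parent_sequences = gen_parent_sequences(seed=spec.seed)

    # parent/position lookup: sites[aa] = [(pdb_id, position), ...]
    sites: dict[str, list[tuple[str, str]]] = {aa: [] for aa in CANONICAL_AA}
    for pdb_id, seq in sorted(parent_sequences.items()):
        for i, aa in enumerate(seq):
            sites[aa].append((pdb_id, str(i + 1)))
    for aa, locs in sites.items():
        rng.shuffle(locs)

    pair_pool: list[list[tuple[str, str]]] = []
    quotas: list[int] = []
    assigned = 0
    for label, frac in spec.category_mix.items():
        pairs = pairs_for_label(label)
        if not pairs:
            raise ValidationError(f"category {label} has no realizing residue pair")
        n = min(int(round(frac * spec.n_records)), spec.n_records - assigned)
        pair_pool.append(pairs)
        quotas.append(n)
        assigned += n
    pair_pool.append(pairs_for_label(CategoryLabel.EVERYTHING))
    quotas.append(spec.n_records - assigned)

    used: set[tuple[str, str, str, str]] = set()
    records: list[MutationRecord] = []
    for pairs, quota in zip(pair_pool, quotas):
        made = 0
        attempts = 0
        while made < quota:
            attempts += 1
            if attempts > 200 * max(1, quota):
                raise ValidationError(
                    "cannot place requested mutations on the parent sequences; "
                    "increase parents/length or lower the mix"
                )
            wt, mut = pairs[rng.integers(len(pairs))]
            if not sites[wt]:
                continue
            pdb_id, pos = sites[wt][rng.integers(len(sites[wt]))]
            key = (pdb_id, pos, wt, mut)
            if key in used:
                continue
            used.add(key)
            comp = rng.choice(3, p=spec.ddg_weights)
            records.append(
                MutationRecord(
                    pdb_id=pdb_id,
                    chain="A",
                    position=pos,
                    wt_aa=wt,
                    mut_aa=mut,
                    ddg_exp=float(rng.normal(spec.ddg_means[comp], spec.ddg_sd)),
                    ph=7.0,
                    source_ref="synthetic",
                )
            )
            made += 1
    return records


def gen_predictions(
    records: Sequence[MutationRecord],
    slope: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    intercept: float = 0.0,
    replicate: int = 1,
) -> list[PredictionRecord]:
    """pred = slope·ΔΔG_exp + intercept + N(0, noise_sd²), seeded."""
    if slope == 0.0 and noise_sd <= 0.0:
        raise ValidationError("need slope ≠ 0 or noise_sd > 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(records)) if noise_sd > 0 else np.zeros(len(records))
    return [
        PredictionRecord(
            record_id=rec.record_id,
            ddg_pred=float(slope * rec.ddg_exp + intercept + noise[i]),
            replicate=replicate,
        )
        for i, rec in enumerate(records)
    ]


# ---------------------------------------------------------------------------
# toy structures


def _helix_atoms(chain: str, sequence: str, origin: np.ndarray) -> list[Atom]:
    """Ideal α-helical backbone trace with Cβ side chains.

    CA atoms on a helix (radius 2.3 Å, rise 1.5 Å/res, 100°/res); N and C
    placed along the CA–CA segments, O off the carbonyl, Cβ radially out.
    Residue names follow ``sequence``; side chains beyond Cβ are omitted.
    """
    from .structure import ONE_TO_THREE

    n_res = len(sequence)
    radius, rise, twist = 2.3, 1.5, math.radians(100.0)
    ca = np.array(
        [
            [radius * math.cos(i * twist), radius * math.sin(i * twist), i * rise]
            for i in range(n_res)
        ]
    ) + origin
    atoms: list[Atom] = []
    for i in range(n_res):
        radial = ca[i] - origin - np.array([0.0, 0.0, i * rise])
        radial = radial / np.linalg.norm(radial)
        prev_dir = (ca[i - 1] - ca[i]) if i > 0 else (ca[i] - ca[i + 1])
        next_dir = (ca[i + 1] - ca[i]) if i < n_res - 1 else (ca[i] - ca[i - 1])
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        pos = str(i + 1)
        coords = {
            "N": ca[i] + 1.45 * prev_dir,
            "CA": ca[i],
            "C": ca[i] + 1.52 * next_dir,
            "O": ca[i] + 1.52 * next_dir + 1.23 * radial,
            "CB": ca[i] + 1.53 * radial,
        }
        res_name = ONE_TO_THREE[sequence[i]]
        if sequence[i] == "G":
            coords.pop("CB")
        for name, xyz in coords.items():
            atoms.append(
                Atom(chain=chain, position=pos, res_name=res_name, atom_name=name,
                     element="N" if name == "N" else ("O" if name == "O" else "C"),
                     x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]))
            )
    return atoms


def gen_two_chain_helices(
    separation: float, chain_lengths: tuple[int, int] = (12, 12)
) -> Structure:
    """Two parallel poly-alanine helices with axes ``separation`` Å apart.

    At large separations no residue has a foreign contact; once the axes
    come within the helices' radial extent plus the cutoff, interface
    residues appear.
    """
    if separation <= 0:
        raise ValidationError(f"separation must be > 0, got {separation}")
    atoms = _helix_atoms("A", "A" * chain_lengths[0], np.zeros(3))
    atoms += _helix_atoms("B", "A" * chain_lengths[1], np.array([separation, 0.0, 0.0]))
    return Structure(atoms=atoms, name=f"helices_sep{separation:g}")


def gen_parent_structures(parent_sequences: Mapping[str, str]) -> dict[str, Structure]:
    """One single-chain helical structure per parent sequence (chain A).

    Gives every synthetic mutation record a parsable parent with its
    wild-type residue at the recorded position, so the full curation
    pipeline (contact filter, burial, dedup) runs on generated data.
    """
    return {
        pdb_id: Structure(
            atoms=_helix_atoms("A", seq, np.zeros(3)), name=pdb_id
        )
        for pdb_id, seq in parent_sequences.items()
    }


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return radius * np.column_stack([r * np.cos(phi * i), r * np.sin(phi * i), z])


def gen_packed_core(verify: bool = True) -> Structure:
    """Single-chain fixture with one fully buried and one exposed residue.

    Residue 1 sits at the origin surrounded by two pseudo-atom shells dense
    enough to occlude it (relative SASA ≤ 0.20); the last residue sits far
    outside the cluster (relative SASA ≥ 0.5).  Geometry is verified at
    generation time.
    """
    atoms: list[Atom] = []

    def add_residue(pos: str, points: np.ndarray):
        names = ["N", "CA", "C", "O", "CB"]
        for j, xyz in enumerate(points):
            name = names[j % 5] if len(points) <= 5 else f"C{j}"
            atoms.append(
                Atom(chain="A", position=pos, res_name="ALA",
                     atom_name=names[j] if len(points) == 5 else name,
                     element="C", x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]))
            )

    # central residue: compact 5-atom cluster at the origin
    central = np.array(
        [[0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [0.0, 1.2, 0.0],
         [0.0, 0.0, 1.2], [-1.0, -1.0, 0.0]]
    ) * 0.9
    add_residue("1", central)

    # occluding shells, grouped into 5-atom pseudo-residues
    shell = np.vstack([_fibonacci_sphere(80, 5.2), _fibonacci_sphere(140, 8.2)])
    for k in range(0, len(shell) - len(shell) % 5, 5):
        add_residue(str(2 + k // 5), shell[k:k + 5])

    # exposed residue far outside the cluster
    exposed_pos = str(2 + len(shell) // 5)
    add_residue(exposed_pos, central + np.array([25.0, 0.0, 0.0]))

    st = Structure(atoms=atoms, name="packed_core")
    if verify:
        buried = relative_sasa(st, "A", "1")
        surface = relative_sasa(st, "A", exposed_pos)
        if buried.relative_sasa > 0.20 or surface.relative_sasa < 0.5:
            raise AssertionError(
                f"packed-core geometry failed verification: "
                f"central {buried.relative_sasa:.3f}, exposed {surface.relative_sasa:.3f}"
            )
    return st
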
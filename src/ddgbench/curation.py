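"""Benchmark construction: filters, deduplication, balancing, composition.

The pipeline turns a raw ProTherm-style mutation table into a categorically
balanced benchmark in a fixed order:

1. row validation (single point mutations only — enforced by the record
   type at read time);
2. structural filters — drop mutations at an inter-chain interface or near
   a non-water ligand (5 Å foreign-atom rule);
3. deduplication — identical mutations on parent backbones sharing ≥60%
   sequence identity collapse to one record, keeping the measurement taken
   at the pH closest to neutral;
4. category balancing — each narrowly defined mutation category is filled
   up to a cap (default 50); superset categories (small↔large, buried,
   surface) are populated only by records selected for the narrow ones.

Re-running the pipeline on its own output is a no-op.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align

from .core import BenchmarkSet, MutationRecord
from .structure import (
    Structure,
    chain_sequence,
    has_foreign_contact,
    residue_relative_sasa_map,
    strip_to_chain,
)
from .taxonomy import (
    CANONICAL_AA,
    CategoryLabel,
    NARROW_CATEGORIES,
    ValidationError,
    classify_mutation,
)

__all__ = [
    "SequenceCluster",
    "CompositionReport",
    "RejectionEntry",
    "sequence_identity",
    "cluster_parents",
    "deduplicate",
    "apply_structure_filters",
    "balance_categories",
    "composition_stats",
    "curate",
]


def _aligner() -> Align.PairwiseAligner:
    # match 1 / mismatch 0 / gap open −1 / gap extend −0.1
    return Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=0.0,
        open_gap_score=-1.0,
        extend_gap_score=-0.1,
    )


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical positions in an optimal global alignment.

    Identity is identities / alignment length (gap columns count in the
    denominator), so unrelated-length sequences are penalised.
    """
    for seq in (a, b):
        if not seq:
            raise ValidationError("empty sequence")
        bad = set(seq.upper()) - CANONICAL_AA
        if bad:
            raise ValidationError(f"non-canonical letters in sequence: {sorted(bad)}")
    aln = _aligner().align(a.upper(), b.upper())[0]
    return aln.counts().identities / aln.length


@dataclass
class SequenceCluster:
    """A single-linkage cluster of parent backbones at an identity threshold."""

    members: list[str]
    identity: dict[tuple[str, str], float] = field(default_factory=dict)

    def __contains__(self, parent_id: str) -> bool:
        return parent_id in self.members


def cluster_parents(
    sequences: Mapping[str, str], threshold: float = 0.60
) -> list[SequenceCluster]:
    """Single-linkage clusters of parents with pairwise identity ≥ threshold."""
    if not sequences:
        raise ValidationError("at least one sequence required")
    parents = sorted(sequences)
    graph = nx.Graph()
    graph.add_nodes_from(parents)
    identity: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(parents, 2):
        ident = sequence_identity(sequences[a], sequences[b])
        identity[(a, b)] = identity[(b, a)] = ident
        if ident >= threshold:
            graph.add_edge(a, b)
    clusters = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        pair_ids = {
            (a, b): identity[(a, b)]
            for a, b in itertools.permutations(members, 2)
        }
        clusters.append(SequenceCluster(members=members, identity=pair_ids))
    return sorted(clusters, key=lambda c: c.members[0])


def _position_columns(
    cluster: SequenceCluster,
    sequences: Mapping[str, str],
    position_lists: Mapping[str, Sequence[str]],
) -> dict[str, dict[str, int]]:
    """Map each member's author positions to alignment columns of a reference.

    The lexicographically first member is the reference; every other member
    is globally aligned to it and author numbering is translated to the
    reference's alignment column, so "the same position" is well defined
    across homologous parents whose numbering differs.
    """
    ref = cluster.members[0]
    maps: dict[str, dict[str, int]] = {}
    aligner = _aligner()
    for member in cluster.members:
        positions = position_lists[member]
        if member == ref:
            maps[member] = {pos: i for i, pos in enumerate(positions)}
            continue
        aln = aligner.align(sequences[ref], sequences[member])[0]
        member_to_ref: dict[int, int] = {}
        for (r0, r1), (m0, m1) in zip(*aln.aligned):
            for off in range(r1 - r0):
                member_to_ref[m0 + off] = r0 + off
        maps[member] = {
            pos: member_to_ref[i]
            for i, pos in enumerate(positions)
            if i in member_to_ref
        }
    return maps


def _ph_sort_key(record: MutationRecord) -> tuple[float, float]:
    # missing pH treated as exactly neutral for selection only
    ph = 7.0 if record.ph is None else record.ph
    return (abs(ph - 7.0), ph)


def deduplicate(
    records: Sequence[MutationRecord],
    clusters: Sequence[SequenceCluster],
    sequences: Mapping[str, str] | None = None,
    position_lists: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[MutationRecord], list["RejectionEntry"]]:
    """Collapse identical mutations within each sequence cluster.

    Two records are duplicates when they share (position, wt, mut) within a
    cluster of parents linked at the identity threshold.  When sequences
    (and the per-parent position lists from :func:`chain_sequence`) are
    available, positions are compared after alignment mapping onto a cluster
    reference; otherwise the raw author numbering is compared.  The survivor
    is the measurement at the pH closest to 7 (ties toward lower pH, then
    first occurrence); records with no pH are treated as pH 7 for selection
    and flagged in the log.  Different mutations at the same position always
    survive independently.
    """
    cluster_of: dict[str, int] = {}
    for ci, cluster in enumerate(clusters):
        for member in cluster.members:
            cluster_of[member] = ci

    colmaps: dict[int, dict[str, dict[str, int]]] = {}
    if sequences is not None and position_lists is not None:
        for ci, cluster in enumerate(clusters):
            if all(m in sequences and m in position_lists for m in cluster.members):
                colmaps[ci] = _position_columns(cluster, sequences, position_lists)

    groups: dict[tuple, list[tuple[int, MutationRecord]]] = {}
    log: list[RejectionEntry] = []
    for i, rec in enumerate(records):
        parent = rec.parent_id
        if parent not in cluster_of:
            raise ValidationError(f"record {rec.record_id}: parent {parent} not clustered")
        ci = cluster_of[parent]
        if ci in colmaps and rec.position in colmaps[ci].get(parent, {}):
            pos_key: object = ("col", colmaps[ci][parent][rec.position])
        else:
            pos_key = ("raw", rec.position)
        groups.setdefault((ci, pos_key, rec.wt_aa, rec.mut_aa), []).append((i, rec))

    kept: list[tuple[int, MutationRecord]] = []
    for group in groups.values():
        order = sorted(group, key=lambda ir: (_ph_sort_key(ir[1]), ir[0]))
        survivor = order[0]
        kept.append(survivor)
        if survivor[1].ph is None:
            log.append(
                RejectionEntry(survivor[1].record_id, "dedup", "kept; pH missing, treated as 7")
            )
        for i, rec in group:
            if i != survivor[0]:
                log.append(
                    RejectionEntry(
                        rec.record_id, "dedup",
                        f"duplicate of {survivor[1].record_id} (pH closest to 7 kept)",
                    )
                )
    kept.sort(key=lambda ir: ir[0])
    return [rec for _, rec in kept], log


@dataclass(frozen=True)
class RejectionEntry:
    record_id: str
    stage: str
    reason: str


def apply_structure_filters(
    records: Sequence[MutationRecord],
    structures: Mapping[str, Structure],
    cutoff: float = 5.0,
) -> tuple[list[MutationRecord], list[RejectionEntry]]:
    """Drop records whose mutated residue touches a foreign atom.

    ``structures`` maps PDB id → full (un-stripped) structure.  A missing
    structure or residue produces a per-record log entry, never a crash.
    """
    kept: list[MutationRecord] = []
    log: list[RejectionEntry] = []
    for rec in records:
        st = structures.get(rec.pdb_id)
        if st is None:
            log.append(RejectionEntry(rec.record_id, "structure_filter", "missing structure"))
            continue
        try:
            contact = has_foreign_contact(st, rec.chain, rec.position, cutoff=cutoff)
        except LookupError as exc:
            log.append(RejectionEntry(rec.record_id, "structure_filter", str(exc)))
            continue
        if contact:
            log.append(
                RejectionEntry(
                    rec.record_id, "structure_filter",
                    f"foreign atom within {cutoff} Å (interface or non-water ligand)",
                )
            )
        else:
            kept.append(rec)
    return kept, log


def balance_categories(
    records: Sequence[MutationRecord],
    cap: int = 50,
    seed: int | None = 0,
    clusters: Sequence[SequenceCluster] | None = None,
    burial: Mapping[str, CategoryLabel] | None = None,
) -> BenchmarkSet:
    """Select records so each narrow category holds min(cap, available) entries.

    Superset categories (Small to large, Large to small, Buried, Surface)
    and the pure aggregates receive no dedicated fill; they are populated by
    whatever the narrow categories selected.  When a category has more than
    ``cap`` unclaimed candidates, selection is seeded random sampling
    stratified by parent cluster so picks spread across unrelated proteins.
    Deterministic for a given seed.
    """
    if cap < 1:
        raise ValidationError(f"cap must be ≥ 1, got {cap}")
    rng = np.random.default_rng(seed)
    cluster_of: dict[str, int] = {}
    if clusters is not None:
        for ci, cluster in enumerate(clusters):
            for member in cluster.members:
                cluster_of[member] = ci

    labels_of = {
        rec.record_id: classify_mutation(rec.wt_aa, rec.mut_aa)
        for rec in records
    }
    selected: set[str] = set()
    counts = {label: 0 for label in NARROW_CATEGORIES}

    def admissible(rec: MutationRecord) -> bool:
        # picking rec must not push any overlapping narrow category past cap
        return all(
            counts[l] < cap
            for l in labels_of[rec.record_id]
            if l in counts
        )

    def pick(rec: MutationRecord) -> None:
        selected.add(rec.record_id)
        for l in labels_of[rec.record_id]:
            if l in counts:
                counts[l] += 1

    for label in NARROW_CATEGORIES:
        need = cap - counts[label]
        if need <= 0:
            continue
        candidates = [
            r for r in records
            if label in labels_of[r.record_id]
            and r.record_id not in selected
            and admissible(r)
        ]
        if len(candidates) <= need:
            for r in candidates:
                pick(r)
            continue
        # stratified draw: cycle clusters in random order, one pick per visit
        by_cluster: dict[object, list[MutationRecord]] = {}
        for r in candidates:
            key = cluster_of.get(r.parent_id, r.parent_id)
            by_cluster.setdefault(key, []).append(r)
        keys = sorted(by_cluster, key=str)
        rng.shuffle(keys)
        for key in keys:
            group = by_cluster[key]
            idx = rng.permutation(len(group))
            by_cluster[key] = [group[i] for i in idx]
        while need > 0:
            progressed = False
            for key in keys:
                if need == 0:
                    break
                while by_cluster[key]:
                    rec = by_cluster[key].pop()
                    if admissible(rec):
                        pick(rec)
                        need -= 1
                        progressed = True
                        break
            if not progressed:
                break

    chosen = [r for r in records if r.record_id in selected]
    return BenchmarkSet.from_records(
        chosen,
        burial=burial,
        provenance={"cap": cap, "seed": seed, "n_input": len(records)},
    )


@dataclass
class CompositionReport:
    """Observed vs expected per-category composition of a mutation set."""

    observed_count: dict[CategoryLabel, int]
    observed_fraction: dict[CategoryLabel, float]
    expected_fraction: dict[CategoryLabel, float]
    n_records: int


def composition_stats(
    records: Sequence[MutationRecord],
    residue_composition: Mapping[str, float],
    burial: Mapping[str, CategoryLabel] | None = None,
) -> CompositionReport:
    """Observed category fractions vs a random-mutation null.

    The null draws the wild-type residue from ``residue_composition`` (the
    amino-acid frequencies of the parent structures) and the mutant
    uniformly from the 19 alternatives; expected fractions follow by
    brute-force summation of :func:`classify_mutation` over all 380 ordered
    pairs.  Burial categories have no sequence-only expectation and are
    reported observed-only (when ``burial`` is given).
    """
    if not records:
        raise ValidationError("composition_stats requires at least one record")
    comp = {aa: float(residue_composition.get(aa, 0.0)) for aa in CANONICAL_AA}
    total = sum(comp.values())
    if total <= 0:
        raise ValidationError("residue_composition sums to zero")
    comp = {aa: f / total for aa, f in comp.items()}

    expected: dict[CategoryLabel, float] = {label: 0.0 for label in CategoryLabel}
    for wt in sorted(CANONICAL_AA):
        for mut in sorted(CANONICAL_AA - {wt}):
            w = comp[wt] / 19.0
            for label in classify_mutation(wt, mut):
                expected[label] += w
    del expected[CategoryLabel.BURIED], expected[CategoryLabel.SURFACE]

    observed: dict[CategoryLabel, int] = {label: 0 for label in CategoryLabel}
    for rec in records:
        b = burial.get(rec.record_id) if burial else None
        for label in classify_mutation(rec.wt_aa, rec.mut_aa, b):
            observed[label] += 1
    n = len(records)
    return CompositionReport(
        observed_count=observed,
        observed_fraction={label: c / n for label, c in observed.items()},
        expected_fraction=expected,
        n_records=n,
    )


def curate(
    records: Sequence[MutationRecord],
    structures: Mapping[str, Structure],
    cap: int = 50,
    identity_threshold: float = 0.60,
    contact_cutoff: float = 5.0,
    seed: int | None = 0,
) -> tuple[BenchmarkSet, list[RejectionEntry]]:
    """Full curation pipeline: structure filters → dedup → balancing.

    Burial (Buried/Surface) is computed on the isolated mutated chain after
    stripping, consistent with the monomer-folding framing of the ΔΔG
    problem.  Returns the benchmark and the rejection/selection log.
    """
    log: list[RejectionEntry] = []
    kept, flog = apply_structure_filters(records, structures, cutoff=contact_cutoff)
    log.extend(flog)

    sequences: dict[str, str] = {}
    position_lists: dict[str, Sequence[str]] = {}
    stripped: dict[str, Structure] = {}
    for rec in kept:
        parent = rec.parent_id
        if parent in sequences:
            continue
        chain_st = strip_to_chain(structures[rec.pdb_id], rec.chain)
        stripped[parent] = chain_st
        seq, positions = chain_sequence(chain_st, rec.chain)
        sequences[parent] = seq
        position_lists[parent] = positions

    if sequences:
        clusters = cluster_parents(sequences, threshold=identity_threshold)
        kept, dlog = deduplicate(kept, clusters, sequences, position_lists)
        log.extend(dlog)
    else:
        clusters = []

    burial: dict[str, CategoryLabel] = {}
    sasa_maps = {
        parent: residue_relative_sasa_map(st, parent.rsplit("_", 1)[-1])
        for parent, st in stripped.items()
    }
    for rec in kept:
        lab = sasa_maps.get(rec.parent_id, {}).get(rec.position)
        if lab is None:
            log.append(RejectionEntry(rec.record_id, "burial", "no burial label"))
            continue
        burial[rec.record_id] = (
            CategoryLabel.BURIED if lab.label == "Buried" else CategoryLabel.SURFACE
        )

    benchmark = balance_categories(
        kept, cap=cap, seed=seed, clusters=clusters, burial=burial
    )
    benchmark.provenance.update(
        identity_threshold=identity_threshold, contact_cutoff=contact_cutoff
    )
    return benchmark, log
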
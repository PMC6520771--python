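"""Species delimitation by pairwise-identity thresholds.

Mitovirus sequences are grouped into putative species by single-linkage
clustering over the percent-identity matrix: strains of one species share
> tau_within (default 86%) nucleotide identity while distinct species
share < tau_between (default 50%).  Threshold comparisons are strict,
matching the ">86%" / "<50%" demarcation phrasing.  The module also
verifies the within/between identity gap, checks that coding regions of
co-specific strains align without indels, and trims contig termini back
to residues supported by at least two strains of the same species.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .align import AlignmentParams, IdentityMatrix, global_align
from .seq_io import NucSeq

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SpeciesPartition:
    """Disjoint, exhaustive clusters of taxa plus the thresholds used."""

    clusters: tuple[frozenset, ...]
    tau_within: float = 86.0
    tau_between: float = 50.0

    def __post_init__(self) -> None:
        all_ids = [t for c in self.clusters for t in c]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("clusters are not disjoint")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, taxon: str) -> int:
        for k, c in enumerate(self.clusters):
            if taxon in c:
                return k
        raise KeyError(taxon)

    def labels(self, ids: Sequence[str]) -> list[int]:
        return [self.cluster_of(t) for t in ids]


@dataclasses.dataclass(frozen=True)
class GapCheck:
    """Result of verifying the within/between identity gap."""

    passed: bool
    min_within: Optional[float]
    max_between: float
    worst_between_pair: Optional[tuple[str, str]]


def cluster_by_identity(
    matrix: IdentityMatrix, tau_within: float = 86.0, tau_between: float = 50.0
) -> SpeciesPartition:
    """Single-linkage clustering: connected components of the graph with an
    edge wherever identity > tau_within (strict)."""
    adj = (matrix.values > tau_within).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for taxon, lab in zip(matrix.ids, labels):
        clusters[lab].append(taxon)
    # deterministic order: by first member's input position
    order = sorted(range(n_comp), key=lambda k: matrix.ids.index(clusters[k][0]))
    return SpeciesPartition(
        clusters=tuple(frozenset(clusters[k]) for k in order),
        tau_within=tau_within,
        tau_between=tau_between,
    )


def check_partition_gap(
    partition: SpeciesPartition, matrix: IdentityMatrix
) -> GapCheck:
    """Verify that intra-cluster identities exceed tau_within and inter-
    cluster identities stay below tau_between (both strict).

    ``min_within`` is undefined (None) when every cluster is a singleton;
    the within-condition is then vacuously satisfied.
    """
    ids = matrix.ids
    label = {t: partition.cluster_of(t) for t in ids}
    min_within: Optional[float] = None
    max_between = -np.inf
    worst: Optional[tuple[str, str]] = None
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = float(matrix.values[i, j])
            if label[ids[i]] == label[ids[j]]:
                if min_within is None or v < min_within:
                    min_within = v
            else:
                if v > max_between:
                    max_between = v
                    worst = (ids[i], ids[j])
    if not np.isfinite(max_between):
        max_between = 0.0
    passed = max_between < partition.tau_between and (
        min_within is None or min_within > partition.tau_within
    )
    if not passed and worst is not None and max_between >= partition.tau_between:
        logger.warning(
            "between-cluster identity %.2f%% for pair %s breaches tau_between=%.1f%%",
            max_between, worst, partition.tau_between,
        )
    return GapCheck(
        passed=passed,
        min_within=min_within,
        max_between=float(max_between),
        worst_between_pair=worst,
    )


def check_cds_indel_free(
    cds_seqs: Sequence[NucSeq], params: AlignmentParams | None = None
) -> tuple[bool, dict[tuple[str, str], int]]:
    """True iff every pairwise global alignment of the coding regions of
    co-specific strains contains zero gap columns (RdRp length conserved
    within a species).  A single strain is vacuously indel-free.

    End gaps are penalized here: the inputs are complete annotated coding
    regions, so a terminal overhang is a real indel, and free end gaps
    would convert terminal substitutions into spurious gap columns."""
    if params is None:
        params = AlignmentParams()
    params = dataclasses.replace(params, end_gaps_penalized=True)
    gap_counts: dict[tuple[str, str], int] = {}
    ok = True
    for i in range(len(cds_seqs)):
        for j in range(i + 1, len(cds_seqs)):
            aln = global_align(cds_seqs[i], cds_seqs[j], params, kind="nucleotide")
            g = aln.n_gap_columns
            gap_counts[(cds_seqs[i].id, cds_seqs[j].id)] = g
            if g:
                ok = False
    return ok, gap_counts


def consensus_trim(
    strains: Sequence[NucSeq], params: AlignmentParams | None = None
) -> list[NucSeq]:
    """Trim contig termini back to residues supported by >= 2 strains.

    Strains are anchored pairwise to the longest strain as the coordinate
    reference.  At each terminus, the outermost reference column at which
    at least two strains carry an identical residue defines the trim
    boundary; residues falling outside the boundaries (including
    insertions relative to the reference) are removed from every strain.
    Idempotent; output lengths never exceed input lengths.
    """
    if len(strains) < 2:
        raise ValueError("consensus trimming needs at least 2 strains")
    if params is None:
        params = AlignmentParams()
    ref_idx = max(range(len(strains)), key=lambda i: len(strains[i]))
    ref = strains[ref_idx]
    n_ref = len(ref)

    # per strain: list of (coordinate, residue); diagonal residues get their
    # reference column, insertions get the half-open coordinate left_col + 0.5
    placed: list[list[tuple[float, str]]] = []
    for s in strains:
        if s.id == ref.id:
            placed.append([(float(c), r) for c, r in enumerate(s.residues)])
            continue
        aln = global_align(s, ref, params, kind="nucleotide")
        coords: list[tuple[float, str]] = []
        r = -1
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if cb != "-":
                r += 1
                if ca != "-":
                    coords.append((float(r), ca))
            elif ca != "-":
                coords.append((r + 0.5, ca))
        placed.append(coords)

    # support per reference column: count of strains sharing the modal residue
    support = np.zeros(n_ref, dtype=np.int64)
    for c in range(n_ref):
        counts: dict[str, int] = {}
        for coords in placed:
            for coord, res in coords:
                if coord == c:
                    counts[res] = counts.get(res, 0) + 1
        if counts:
            support[c] = max(counts.values())

    supported = np.nonzero(support >= 2)[0]
    if supported.size == 0:
        logger.warning("no reference column supported by >=2 strains; not trimming")
        return list(strains)
    b5, b3 = int(supported[0]), int(supported[-1])

    trimmed = []
    for s, coords in zip(strains, placed):
        kept = "".join(res for coord, res in coords if b5 <= coord <= b3)
        trimmed.append(NucSeq(id=s.id, residues=kept, source=s.source))
    return trimmed
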
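"""End-to-end orchestration of the characterization analysis.

``run_characterize`` produces the per-sequence annotation/codon report
(total length, NTRs, protein length, completeness, Trp UGA/UGG counts);
``run_delimit`` chains identity matrix -> threshold clustering -> gap
check -> per-cluster indel check -> protein-distance NJ tree.  Both are
pure functions over in-memory sequences; the CLI is a thin wrapper.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from .align import AlignmentParams, IdentityMatrix, identity_matrix
from .codon_stats import codon_usage
from .delimit import (
    GapCheck,
    SpeciesPartition,
    check_cds_indel_free,
    check_partition_gap,
    cluster_by_identity,
)
from .genetic_code import GeneticCode, get_code
from .orf import NoOrfFound, assess_completeness, find_primary_orf
from .phylo import midpoint_root, neighbor_joining, p_distance_matrix, to_newick
from .seq_io import NucSeq

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Shared pipeline configuration."""

    code_id: int = 4
    params: AlignmentParams = dataclasses.field(default_factory=AlignmentParams)
    tau_within: float = 86.0
    tau_between: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.tau_between < self.tau_within < 100):
            raise ValueError("require 0 < tau_between < tau_within < 100")

    @property
    def code(self) -> GeneticCode:
        return get_code(self.code_id)


def characterize_row(seq: NucSeq, code: GeneticCode) -> dict:
    """One annotation-report row (the machine-readable twin of a
    per-sequence summary-figure entry)."""
    try:
        orf = find_primary_orf(seq, code)
    except NoOrfFound:
        return {"seq_id": seq.id, "status": "NO_ORF", "total_nt": len(seq)}
    usage = codon_usage(seq.residues[orf.cds[0] : orf.cds[1]], code, seq_id=seq.id)
    return {
        "seq_id": seq.id,
        "status": "OK",
        "total_nt": len(seq),
        "ntr5_nt": orf.ntr5_len,
        "ntr3_nt": orf.ntr3_len,
        "orf_nt": orf.end - orf.start,
        "protein_aa": len(orf.protein),
        "start_codon": orf.start_codon,
        "completeness": assess_completeness(orf),
        "trp_uga": usage.trp_uga,
        "trp_ugg": usage.trp_ugg,
        "pct_uga": usage.pct_uga if usage.pct_uga is not None else "",
    }


@dataclasses.dataclass(frozen=True)
class CharacterizeResult:
    rows: tuple[dict, ...]
    summary: dict

    def write_tsv(self, path) -> None:
        from .seq_io import write_tsv

        columns = [
            "seq_id", "status", "total_nt", "ntr5_nt", "ntr3_nt", "orf_nt",
            "protein_aa", "start_codon", "completeness", "trp_uga",
            "trp_ugg", "pct_uga",
        ]
        write_tsv(list(self.rows), path, columns=columns)


def run_characterize(
    seqs: Sequence[NucSeq], config: RunConfig | None = None
) -> CharacterizeResult:
    """Annotate every input and summarize the per-sequence statistics."""
    config = config or RunConfig()
    rows = [characterize_row(s, config.code) for s in seqs]
    ok = [r for r in rows if r["status"] == "OK"]
    for r in rows:
        if r["status"] != "OK":
            logger.warning("no ORF found in %s; excluded from summaries", r["seq_id"])
    summary = {}
    for col in ("total_nt", "ntr5_nt", "ntr3_nt", "protein_aa", "trp_uga", "trp_ugg"):
        vals = np.array([r[col] for r in ok]) if ok else np.array([0])
        summary[col] = {
            "min": int(vals.min()),
            "max": int(vals.max()),
            "median": float(np.median(vals)),
        }
    summary["n_sequences"] = len(rows)
    summary["n_annotated"] = len(ok)
    return CharacterizeResult(rows=tuple(rows), summary=summary)


@dataclasses.dataclass(frozen=True)
class DelimitResult:
    matrix: IdentityMatrix
    partition: SpeciesPartition
    gap_check: GapCheck
    indel_free: dict[int, bool]
    newick: str


def run_delimit(
    seqs: Sequence[NucSeq], config: RunConfig | None = None
) -> DelimitResult:
    """Cluster sequences into putative species and build the strain tree.

    Chains identity_matrix -> cluster_by_identity -> check_partition_gap ->
    per-cluster check_cds_indel_free -> protein p-distance NJ, midpoint
    rooted, serialized as Newick.
    """
    config = config or RunConfig()
    if len(seqs) < 2:
        raise ValueError("delimitation needs at least 2 sequences")
    code = config.code

    matrix = identity_matrix(seqs, config.params)
    partition = cluster_by_identity(matrix, config.tau_within, config.tau_between)
    gap = check_partition_gap(partition, matrix)

    by_id = {s.id: s for s in seqs}
    orfs = {}
    for s in seqs:
        try:
            orfs[s.id] = find_primary_orf(s, code)
        except NoOrfFound:
            logger.warning("delimit: no ORF in %s", s.id)

    indel_free: dict[int, bool] = {}
    for k, cluster in enumerate(partition.clusters):
        members = [m for m in cluster if m in orfs]
        cds_seqs = [
            NucSeq(id=m, residues=by_id[m].residues[slice(*orfs[m].cds)])
            for m in sorted(members)
        ]
        if len(cds_seqs) < 2:
            indel_free[k] = True
        else:
            indel_free[k], _ = check_cds_indel_free(cds_seqs, config.params)

    proteins = {s.id: orfs[s.id].protein for s in seqs if s.id in orfs}
    if len(proteins) >= 2:
        dm = p_distance_matrix(proteins, config.params)
        tree = midpoint_root(neighbor_joining(dm))
        newick = to_newick(tree)
    else:
        newick = ""
    return DelimitResult(
        matrix=matrix,
        partition=partition,
        gap_check=gap,
        indel_free=indel_free,
        newick=newick,
    )
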
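"""Codon-usage statistics, centered on Trp UGA-vs-UGG usage.

Under mitochondrial code 4 tryptophan is encoded by both UGG and the
reassigned stop codon UGA; the fraction of Trp codons read from UGA is
the key usage statistic for deciding whether UGA(Trp) is a rarely used
codon in a mitochondrial system.  Counts cover coding codons only (the
terminal stop is excluded by contract: callers pass the coding region),
and codons containing ambiguity letters are excluded from counts and
tallied separately.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from .genetic_code import GeneticCode, get_code
from .orf import UNAMBIGUOUS


@dataclasses.dataclass(frozen=True)
class CodonUsageProfile:
    """Per-CDS codon counts and Trp UGA/UGG statistics.

    ``trp_uga_fraction`` is None (undefined) when the CDS encodes no Trp.
    ``uga_positions`` are 0-based codon indices within the CDS.
    """

    seq_id: str
    counts: dict
    n_ambiguous: int
    trp_uga: int
    trp_ugg: int
    uga_positions: tuple[int, ...]

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def trp_uga_fraction(self) -> Optional[float]:
        total = self.trp_uga + self.trp_ugg
        if total == 0:
            return None
        return self.trp_uga / total

    @property
    def pct_uga(self) -> Optional[int]:
        """Percent UGA among Trp codons, rounded to the nearest integer."""
        f = self.trp_uga_fraction
        return None if f is None else round(100 * f)


def codon_usage(
    cds: str, code: GeneticCode | int = 4, seq_id: str = ""
) -> CodonUsageProfile:
    """Tally codon usage over a coding region (terminal stop excluded by
    the caller)."""
    if isinstance(code, int):
        code = get_code(code)
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    counts: dict[str, int] = {}
    n_ambiguous = 0
    uga_positions = []
    for idx in range(len(cds) // 3):
        codon = cds[3 * idx : 3 * idx + 3]
        if set(codon) <= UNAMBIGUOUS:
            counts[codon] = counts.get(codon, 0) + 1
            if codon == "UGA":
                uga_positions.append(idx)
        else:
            n_ambiguous += 1
    return CodonUsageProfile(
        seq_id=seq_id,
        counts=counts,
        n_ambiguous=n_ambiguous,
        trp_uga=counts.get("UGA", 0),
        trp_ugg=counts.get("UGG", 0),
        uga_positions=tuple(uga_positions),
    )


def pool_trp_stats(
    profiles: Sequence[CodonUsageProfile],
) -> tuple[int, int, Optional[float]]:
    """Pool Trp codon counts across CDSs: sum counts, then recompute the
    fraction (not the mean of per-CDS fractions)."""
    if not profiles:
        raise ValueError("need at least one profile")
    uga = sum(p.trp_uga for p in profiles)
    ugg = sum(p.trp_ugg for p in profiles)
    fraction = uga / (uga + ugg) if (uga + ugg) else None
    return uga, ugg, fraction


def uga_position_conservation(
    cds_seqs: Sequence[str],
    code: GeneticCode | int = 4,
    params=None,
) -> Optional[float]:
    """Fraction of UGA codon sites shared by all homologous CDS copies.

    The first CDS serves as the coordinate reference; UGA nucleotide
    positions in the other copies are mapped through pairwise global
    alignment onto reference coordinates.  Returns shared-site count /
    union-site count, or None when no copy contains a UGA.
    """
    from .align import global_align

    if len(cds_seqs) < 2:
        raise ValueError("conservation needs at least 2 CDS copies")
    if isinstance(code, int):
        code = get_code(code)

    ref = cds_seqs[0]

    def uga_ref_coords(cds: str) -> set[int]:
        prof = codon_usage(cds, code)
        nt_pos = {3 * i for i in prof.uga_positions}
        if cds == ref:
            return nt_pos
        aln = global_align(cds, ref, params, kind="nucleotide")
        mapping: dict[int, int] = {}
        qi = ri = -1
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca != "-":
                qi += 1
            if cb != "-":
                ri += 1
            if ca != "-" and cb != "-":
                mapping[qi] = ri
        return {mapping[p] for p in nt_pos if p in mapping}

    sites = [uga_ref_coords(c) for c in cds_seqs]
    union = set().union(*sites)
    if not union:
        return None
    shared = set(sites[0]).intersection(*sites[1:])
    return len(shared) / len(union)
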
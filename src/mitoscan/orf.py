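"""Primary-ORF annotation under a configurable genetic code.

A mitovirus genome is a plus-strand RNA of 2.0-4.5 kb carrying a single
long ORF (the RdRp) that, under mitochondrial code 4, uses UGA for Trp.
This module scans the three plus-strand frames, annotates the longest
AUG-initiated ORF, measures the flanking nontranslated regions (NTRs),
classifies coding completeness from the presence of in-frame stop codons
on both flanks, and proposes alternative (non-first-AUG) start codons.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from .genetic_code import STOP, GeneticCode, get_code
from .seq_io import NucSeq

UNAMBIGUOUS = frozenset("ACGU")


class NoOrfFound(ValueError):
    """No AUG-initiated ORF exists in any plus-strand frame."""


@dataclasses.dataclass(frozen=True)
class OrfAnnotation:
    """Annotation of the primary (longest) AUG-initiated ORF of a contig.

    ``start`` is the first base of the start codon; ``end`` is one past the
    last base of the terminal stop codon when the ORF is stop-terminated,
    else one past the last complete codon.  ``upstream_stop_end`` is the
    end (exclusive) of the nearest upstream in-frame stop codon, or None
    when the reading frame runs off the 5' end of the contig first.
    """

    seq_id: str
    frame: int
    start: int
    end: int
    start_codon: str
    has_terminal_stop: bool
    upstream_stop_end: Optional[int]
    protein: str
    ntr5_len: int
    ntr3_len: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF span not divisible by 3")
        n_codons = (self.end - self.start) // 3
        expect = n_codons - (1 if self.has_terminal_stop else 0)
        if len(self.protein) != expect:
            raise ValueError("protein length inconsistent with ORF span")

    @property
    def cds(self) -> tuple[int, int]:
        """Coding region (start codon through last sense codon), half-open."""
        return self.start, self.end - (3 if self.has_terminal_stop else 0)


class CompletenessCall:
    """Coding-completeness categories for an annotated contig."""

    CODING_COMPLETE_BOTH_FLANKS = "CODING_COMPLETE_BOTH_FLANKS"
    CODING_COMPLETE_NO_UPSTREAM_STOP = "CODING_COMPLETE_NO_UPSTREAM_STOP"
    INCOMPLETE_3PRIME = "INCOMPLETE_3PRIME"


@dataclasses.dataclass(frozen=True)
class StartProposal:
    """A proposed alternative start codon for one taxon.

    ``delta_aa`` is the signed change in protein length relative to the
    first-AUG convention (positive for upstream starts).  ``support`` counts
    other taxa sharing the conserved N-terminal residues that motivated the
    proposal (0 when the proposal was not conservation-scored).  The
    initiator residue is reported as the plain table amino acid (V for GUG,
    I for AUU); whether the initiator is read as fMet is a translation-
    system question this annotation does not decide.
    """

    seq_id: str
    proposed_start: int
    proposed_codon: str
    delta_aa: int
    support: int = 0


def translate(cds: str, code: GeneticCode | int = 4) -> str:
    """Translate an RNA coding sequence codon by codon.

    Stops render as ``'*'``; any codon containing a non-ACGU letter renders
    as ``'X'`` (coverage gaps are untranslatable, never start/stop).
    """
    code = _as_code(code)
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if set(codon) <= UNAMBIGUOUS:
            out.append(code.table[codon])
        else:
            out.append("X")
    return "".join(out)


def _as_code(code: GeneticCode | int) -> GeneticCode:
    return code if isinstance(code, GeneticCode) else get_code(code)


def find_primary_orf(seq: NucSeq, code: GeneticCode | int = 4) -> OrfAnnotation:
    """Locate the longest AUG-initiated ORF across the three plus-strand frames.

    Within each frame, segments are bounded by in-frame stop codons and the
    sequence ends; the candidate in each segment runs from the segment's
    first AUG through the closing stop (inclusive), or through the last
    complete codon when unterminated.  The candidate maximizing ``end -
    start`` wins (a stop-terminated ORF therefore beats an unterminated one
    of equal coding length); ties break toward smaller start, then smaller
    frame.  Codons containing ambiguity letters never match start or stop.
    """
    code = _as_code(code)
    res = seq.residues
    n = len(res)
    if n < 6:
        raise ValueError("sequence shorter than 6 nt")
    stops = code.stop_codons

    best: tuple[int, int, int, bool, Optional[int]] | None = None

    def consider(start: int, end: int, frame: int, terminated: bool,
                 upstream: Optional[int]) -> None:
        nonlocal best
        if best is None:
            best = (start, end, frame, terminated, upstream)
            return
        b_len, c_len = best[1] - best[0], end - start
        if (c_len, -start, -frame) > (b_len, -best[0], -best[2]):
            best = (start, end, frame, terminated, upstream)

    for frame in range(3):
        first_aug: Optional[int] = None
        upstream: Optional[int] = None  # end of the stop opening this segment
        last_codon_end = frame
        for pos in range(frame, n - 2, 3):
            codon = res[pos : pos + 3]
            last_codon_end = pos + 3
            if codon in stops:
                if first_aug is not None:
                    consider(first_aug, pos + 3, frame, True, upstream)
                upstream = pos + 3
                first_aug = None
            elif codon == "AUG" and first_aug is None:
                first_aug = pos
        if first_aug is not None:
            consider(first_aug, last_codon_end, frame, False, upstream)

    if best is None:
        raise NoOrfFound(f"no AUG-initiated ORF in any frame of {seq.id!r}")

    start, end, frame, terminated, upstream = best
    coding_end = end - (3 if terminated else 0)
    protein = translate(res[start:coding_end], code)
    return OrfAnnotation(
        seq_id=seq.id,
        frame=frame,
        start=start,
        end=end,
        start_codon=res[start : start + 3],
        has_terminal_stop=terminated,
        upstream_stop_end=upstream,
        protein=protein,
        ntr5_len=start,
        ntr3_len=n - end,
    )


def assess_completeness(orf: OrfAnnotation) -> str:
    """Classify coding completeness from the stop codons flanking the ORF.

    A contig is coding complete when an in-frame stop terminates the ORF;
    an additional in-frame stop upstream of the start codon shows that no
    longer N-terminally extended product can be encoded.
    """
    if not orf.has_terminal_stop:
        return CompletenessCall.INCOMPLETE_3PRIME
    if orf.upstream_stop_end is not None:
        return CompletenessCall.CODING_COMPLETE_BOTH_FLANKS
    return CompletenessCall.CODING_COMPLETE_NO_UPSTREAM_STOP


def extend_with_alternative_start(
    seq: NucSeq, orf: OrfAnnotation, code: GeneticCode | int = 4
) -> list[StartProposal]:
    """Enumerate in-frame alternative start codons upstream of the first AUG.

    Scans every in-frame codon strictly between the nearest upstream
    in-frame stop (or the first complete in-frame codon of the contig) and
    the current start for canonical or alternative initiators (AUG, GUG,
    AUU by default).  Each hit yields a proposal with positive ``delta_aa``.
    Sorted by position ascending.
    """
    code = _as_code(code)
    res = seq.residues
    lower = orf.upstream_stop_end if orf.upstream_stop_end is not None else orf.start % 3
    proposals = []
    for pos in range(lower, orf.start, 3):
        codon = res[pos : pos + 3]
        if codon in code.start_codons:
            proposals.append(
                StartProposal(
                    seq_id=orf.seq_id,
                    proposed_start=pos,
                    proposed_codon=codon,
                    delta_aa=(orf.start - pos) // 3,
                )
            )
    return proposals


def _downstream_aug_starts(
    seq: NucSeq, orf: OrfAnnotation, max_rank: int = 3
) -> list[int]:
    """Positions of the 2nd..max_rank-th in-frame AUGs within the ORF."""
    res = seq.residues
    out = []
    rank = 1  # the ORF start itself is the 1st AUG
    cds_start, cds_end = orf.cds
    for pos in range(cds_start + 3, cds_end, 3):
        if res[pos : pos + 3] == "AUG":
            rank += 1
            if rank > max_rank:
                break
            out.append(pos)
    return out


def propose_start_by_conservation(
    taxa: Sequence[tuple[NucSeq, OrfAnnotation]],
    code: GeneticCode | int = 4,
    min_support: int = 2,
    window: int = 30,
    params=None,
) -> list[StartProposal]:
    """Refine start-codon calls by N-terminal conservation across taxa.

    For each taxon, candidate starts (the first-AUG baseline, upstream
    alternative initiators, and downstream in-frame AUGs up to the 3rd) are
    scored against the other taxa after pairwise global protein alignment
    to the longest taxon: the score is the number of reference columns in
    the N-terminal window whose residue is shared by >= ``min_support``
    taxa.  Ties break toward the candidate with the fewest leading
    unshared residues.  When the first-AUG convention already maximizes
    the score, no proposal is emitted for that taxon.

    This is one concrete formalization of an informal conservation
    argument; the window and support threshold are configurable.
    """
    from .align import AlignmentParams, global_align

    if len(taxa) < 2:
        raise ValueError("conservation scoring needs at least 2 taxa")
    if params is None:
        params = AlignmentParams()
    code = _as_code(code)

    ref_idx = max(range(len(taxa)), key=lambda i: len(taxa[i][1].protein))
    ref_protein = taxa[ref_idx][1].protein

    def map_to_ref(protein: str) -> dict[int, str]:
        """Map reference-column index -> this protein's residue (diag cols)."""
        if protein == ref_protein:
            return dict(enumerate(protein))
        aln = global_align(protein, ref_protein, params, kind="protein")
        mapping: dict[int, str] = {}
        r = -1
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if cb != "-":
                r += 1
                if ca != "-":
                    mapping[r] = ca
        return mapping

    baseline_maps = [map_to_ref(orf.protein) for _, orf in taxa]

    def leading_unshared(mapping: dict[int, str], shared_cols: set[int]) -> int:
        cols = sorted(mapping)
        count = 0
        for c in cols:
            if c in shared_cols and c < window:
                break
            count += 1
        return count

    def score(t: int, mapping: dict[int, str]) -> tuple[int, int, set[int]]:
        shared_cols: set[int] = set()
        for c in range(min(window, len(ref_protein))):
            residue = mapping.get(c)
            if residue is None:
                continue
            n_shared = 1 + sum(
                1
                for j, bm in enumerate(baseline_maps)
                if j != t and bm.get(c) == residue
            )
            if n_shared >= min_support:
                shared_cols.add(c)
        return len(shared_cols), -leading_unshared(mapping, shared_cols), shared_cols

    proposals: list[StartProposal] = []
    for t, (seq, orf) in enumerate(taxa):
        candidates: list[tuple[Optional[StartProposal], str]] = [(None, orf.protein)]
        for prop in extend_with_alternative_start(seq, orf, code):
            cand_cds = seq.residues[prop.proposed_start : orf.cds[1]]
            candidates.append((prop, translate(cand_cds, code)))
        for pos in _downstream_aug_starts(seq, orf):
            prop = StartProposal(
                seq_id=orf.seq_id,
                proposed_start=pos,
                proposed_codon="AUG",
                delta_aa=-(pos - orf.start) // 3,
            )
            candidates.append((prop, orf.protein[(pos - orf.start) // 3 :]))

        best_prop, best_key, best_shared = None, None, None
        for prop, protein in candidates:
            mapping = map_to_ref(protein) if prop is not None else baseline_maps[t]
            s, neg_lead, shared = score(t, mapping)
            key = (s, neg_lead)
            # strict improvement required to displace the first-AUG baseline
            if best_key is None or key > best_key:
                best_prop, best_key, best_shared = prop, key, shared
        if best_prop is not None:
            baseline_shared = score(t, baseline_maps[t])[2]
            gained = best_shared - baseline_shared
            cols = gained if gained else best_shared
            support = 0
            if cols:
                support = min(
                    sum(
                        1
                        for j, bm in enumerate(baseline_maps)
                        if j != t and bm.get(c) is not None
                        and bm.get(c) == _candidate_residue(best_prop, taxa[t], c,
                                                           code, map_to_ref)
                    )
                    for c in cols
                )
            proposals.append(dataclasses.replace(best_prop, support=support))
    return proposals


def _candidate_residue(prop, taxon, col, code, map_to_ref):
    seq, orf = taxon
    if prop.delta_aa >= 0:
        protein = translate(seq.residues[prop.proposed_start : orf.cds[1]], code)
    else:
        protein = orf.protein[-prop.delta_aa :]
    return map_to_ref(protein).get(col)
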
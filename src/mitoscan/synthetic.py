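"""Seeded generators for mitovirus-like genomes and mitochondrial-core-gene
transcripts with tracked ground truth.

The mitovirus generator emulates the genome architecture of the study
system: a plus-strand RNA of ~2.3-2.8 kb carrying a single long ORF under
mitochondrial code 4 (product 636-757 aa), a long 5' NTR (105-477 nt)
containing an in-frame stop upstream of the first AUG, a short 3' NTR
(1-175 nt), and 10-17 Trp codons of which a 0.38-0.77 fraction are UGA.
Strains of one species differ by coding-region substitutions only
(synonymous-biased, never creating stops) calibrated to a pairwise
identity target, plus optional small NTR indels biased toward the 5' NTR;
distinct species are independent draws sharing only these architectural
constraints.  Every emitted genome is re-annotated at generation time and
checked against its own truth record, so the generator cannot emit
inconsistent fixtures.

The core-gene generator emulates a 12-gene mitochondrial transcript set
(atp6..nad6) with a designed pooled Trp-UGA fraction, including a cox1
whose true start is an upstream in-frame GUG extending the product to
528 aa relative to the first-AUG convention.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional, Sequence

import numpy as np

from .codon_stats import codon_usage
from .genetic_code import get_code
from .orf import OrfAnnotation, find_primary_orf, translate
from .seq_io import NucSeq

_CODE4 = get_code(4)
_STOPS = sorted(_CODE4.stop_codons)  # UAA, UAG
_ALL = ["".join(c) for c in itertools.product("ACGU", repeat=3)]
#: sense codons that encode neither Trp nor stop (code 4)
_BACKGROUND = [c for c in _ALL if c not in {"UAA", "UAG", "UGA", "UGG"}]
_BACKGROUND_NO_AUG = [c for c in _BACKGROUND if c != "AUG"]
_NT = np.array(list("ACGU"))


class InfeasibleSpec(ValueError):
    """The requested genome architecture cannot be realized."""


@dataclasses.dataclass(frozen=True)
class MitovirusSpec:
    """Sampling ranges for synthetic mitovirus genomes (study conditions).

    Ranges are inclusive; per-genome values are drawn uniformly.
    ``strain_identity_target`` is the target *pairwise* nucleotide identity
    between strains of one species; ``species_identity_target`` documents
    the expected ceiling for between-species identity (independent draws
    land well below it and it is not otherwise enforced).
    """

    n_species: int = 8
    strains_per_species: int = 4
    protein_len: tuple[int, int] = (636, 757)
    ntr5_len: tuple[int, int] = (105, 477)
    ntr3_len: tuple[int, int] = (1, 175)
    trp_count: tuple[int, int] = (10, 17)
    trp_uga_fraction: tuple[float, float] = (0.38, 0.77)
    strain_identity_target: tuple[float, float] = (0.87, 0.99)
    species_identity_target: float = 0.45
    ntr_indels_between_strains: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("protein_len", "ntr5_len", "ntr3_len", "trp_count"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise InfeasibleSpec(f"bad range for {name}: {(lo, hi)}")
        if self.trp_count[1] >= self.protein_len[0]:
            raise InfeasibleSpec("protein too short for requested Trp count")
        lo, hi = self.trp_uga_fraction
        if not (0 <= lo <= hi <= 1):
            raise InfeasibleSpec("trp_uga_fraction must lie in [0, 1]")
        if self.strain_identity_target[0] <= self.species_identity_target:
            raise InfeasibleSpec("strain identity target must exceed species target")


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """Generator ground truth for one emitted genome (re-annotation-checked)."""

    seq_id: str
    species_id: str
    orf_start: int
    orf_end: int
    protein: str
    trp_uga: int
    trp_ugg: int
    substitution_positions: tuple[int, ...]  # CDS-relative nt positions
    identity_target: Optional[float] = None


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _pick(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.integers(0, len(items)))]


def _design_cds(
    rng: np.random.Generator,
    protein_len: int,
    trp_count: int,
    n_uga: int,
    no_aug_codons: Sequence[int] = (),
    start_codon: str = "AUG",
) -> list[str]:
    """Build a coding region (list of codons incl. terminal stop) with an
    exact Trp composition."""
    codons = [start_codon]
    positions = 1 + rng.permutation(protein_len - 1)[:trp_count]
    uga_set = set(positions[:n_uga].tolist())
    trp_set = set(positions.tolist())
    banned = set(no_aug_codons)
    for i in range(1, protein_len):
        if i in trp_set:
            codons.append("UGA" if i in uga_set else "UGG")
        elif i in banned:
            codons.append(_pick(rng, _BACKGROUND_NO_AUG))
        else:
            codons.append(_pick(rng, _BACKGROUND))
    codons.append(_pick(rng, _STOPS))
    return codons


def _design_ntr5(
    rng: np.random.Generator, length: int, scrub_starts: bool = False
) -> tuple[str, int]:
    """Random 5' NTR with an in-frame stop upstream of the CDS; returns the
    NTR and the position of the designed upstream stop.  In-frame AUGs
    between that stop and the CDS are scrubbed (they would move the
    annotated start); with ``scrub_starts`` alternative initiators (GUG,
    AUU) in that window are scrubbed as well."""
    ntr = list(_rand_nt(rng, length))
    frame_positions = [p for p in range(length % 3, length - 2, 3)]
    if not frame_positions:
        raise InfeasibleSpec("5' NTR too short to host an upstream stop")
    # place the stop among the in-frame codons nearest the CDS
    tail = frame_positions[-min(10, len(frame_positions)):]
    stop_pos = tail[int(rng.integers(0, len(tail)))]
    ntr[stop_pos : stop_pos + 3] = list(_pick(rng, _STOPS))
    banned = {"AUG", "GUG", "AUU"} if scrub_starts else {"AUG"}
    for p in range(stop_pos + 3, length - 2, 3):
        while "".join(ntr[p : p + 3]) in banned:
            ntr[p] = _pick(rng, "ACGU")
    return "".join(ntr), stop_pos


def _annotate_and_check(
    seq: NucSeq, expect_start: int, expect_protein: str
) -> OrfAnnotation:
    orf = find_primary_orf(seq, _CODE4)
    if orf.start != expect_start or orf.protein != expect_protein:
        raise _SelfCheckFailed()
    if not orf.has_terminal_stop or orf.upstream_stop_end is None:
        raise _SelfCheckFailed()
    return orf


class _SelfCheckFailed(Exception):
    pass


def _make_ancestor(rng: np.random.Generator, spec: MitovirusSpec):
    """One species ancestor; rejection-sampled until self-check passes."""
    for _ in range(100):
        L = int(rng.integers(spec.protein_len[0], spec.protein_len[1] + 1))
        trp = int(rng.integers(spec.trp_count[0], spec.trp_count[1] + 1))
        frac = rng.uniform(*spec.trp_uga_fraction)
        n_uga = int(round(trp * frac))
        ntr5_len = int(rng.integers(spec.ntr5_len[0], spec.ntr5_len[1] + 1))
        ntr3_len = int(rng.integers(spec.ntr3_len[0], spec.ntr3_len[1] + 1))
        codons = _design_cds(rng, L, trp, n_uga)
        ntr5, stop_pos = _design_ntr5(rng, ntr5_len)
        ntr3 = _rand_nt(rng, ntr3_len)
        genome = ntr5 + "".join(codons) + ntr3
        protein = translate("".join(codons[:-1]), _CODE4)
        try:
            _annotate_and_check(
                NucSeq(id="anc", residues=genome), ntr5_len, protein
            )
        except _SelfCheckFailed:
            continue
        return genome, ntr5_len, L, stop_pos
    raise InfeasibleSpec("could not realize an ancestor for this spec")


def _mutate_cds(
    rng: np.random.Generator,
    genome: list[str],
    cds_start: int,
    positions: Sequence[int],
    synonymous_bias: float = 0.75,
) -> None:
    """Apply one substitution at each genome position, in place.  Never
    touches the start codon, never creates an in-frame stop, and preserves
    Trp-ness (the designed Trp-codon composition is an architectural
    constraint; a UGA<->UGG swap is the only change allowed at a Trp
    codon); synonymous changes are preferred where available."""
    for p in positions:
        codon_start = cds_start + 3 * ((p - cds_start) // 3)
        offset = p - codon_start
        codon = "".join(genome[codon_start : codon_start + 3])
        aa = _CODE4.table[codon]
        syn, nonsyn = [], []
        for base in "ACGU":
            if base == codon[offset]:
                continue
            alt = codon[:offset] + base + codon[offset + 1 :]
            if _CODE4.is_stop(alt):
                continue
            alt_aa = _CODE4.table[alt]
            if (alt_aa == "W") != (aa == "W"):
                continue
            (syn if alt_aa == aa else nonsyn).append(base)
        if syn and (not nonsyn or rng.random() < synonymous_bias):
            pool = syn
        else:
            pool = nonsyn or syn
        genome[p] = _pick(rng, pool)


def _apply_ntr_indels(
    rng: np.random.Generator,
    genome: str,
    stop_pos: int,
    orf_end: int,
) -> str:
    """Small indels in the NTRs, 5'-biased; 5' indels stay strictly
    upstream of the designed upstream stop so the ORF architecture is
    untouched, 3' indels stay past the ORF end."""
    n5 = int(rng.choice([0, 1, 2], p=[0.3, 0.45, 0.25]))
    n3 = int(rng.choice([0, 1], p=[0.6, 0.4]))
    s = genome
    shift = 0
    for _ in range(n5):
        room = stop_pos + shift - 4
        if room < 4:
            break
        pos = int(rng.integers(2, room))
        length = int(rng.integers(1, 5))
        if rng.random() < 0.5:
            s = s[:pos] + _rand_nt(rng, length) + s[pos:]
            shift += length
        else:
            length = min(length, room - pos)
            s = s[:pos] + s[pos + length :]
            shift -= length
    end = orf_end + shift
    for _ in range(n3):
        if len(s) - end < 6:
            break
        pos = int(rng.integers(end + 1, len(s) - 1))
        length = int(rng.integers(1, 5))
        if rng.random() < 0.5:
            s = s[:pos] + _rand_nt(rng, length) + s[pos:]
        else:
            length = min(length, len(s) - pos - 1)
            s = s[:pos] + s[pos + length :]
    return s


def generate_dataset(
    spec: MitovirusSpec,
) -> tuple[list[NucSeq], list[TruthRecord]]:
    """Generate a strain collection of synthetic mitovirus genomes.

    Returns the genomes (species-major order, ids ``SP<k>-S<j>``) and one
    truth record per genome.  Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    seqs: list[NucSeq] = []
    truths: list[TruthRecord] = []

    for sp in range(spec.n_species):
        species_id = f"SP{sp + 1}"
        genome, ntr5_len, L, stop_pos = _make_ancestor(rng, spec)
        n = len(genome)
        cds_start = ntr5_len
        orf_end = ntr5_len + 3 * (L + 1)

        # disjoint substitution positions across strains -> pairwise
        # differences are exactly additive.  Positions are third codon
        # positions (purifying selection leaves divergence overwhelmingly
        # synonymous), which also keeps mismatches isolated so optimal
        # alignment of strain CDSs stays gap-free; first codon positions
        # not adjacent to a chosen third position serve as overflow.
        trp_codons = {
            ci for ci in range(L)
            if genome[cds_start + 3 * ci : cds_start + 3 * ci + 3]
            in ("UGA", "UGG")
        }
        # Trp codons are frozen: their number, UGA/UGG split, and positions
        # are conserved among strains (as observed across isolates)
        third = np.array(
            [p for p in range(cds_start + 5, cds_start + 3 * L, 3)
             if (p - cds_start) // 3 not in trp_codons],
            dtype=np.int64,
        )
        first = np.array(
            [p for p in range(cds_start + 3, cds_start + 3 * L, 3)
             if (p - cds_start) // 3 not in trp_codons],
            dtype=np.int64,
        )
        pool = third[rng.permutation(third.size)]
        overflow = first[rng.permutation(first.size)]
        cursor = 0

        for st in range(spec.strains_per_species):
            seq_id = f"{species_id}-S{st + 1}"
            target = rng.uniform(*spec.strain_identity_target)
            k = int(round((1.0 - target) / 2.0 * n))
            if cursor + k > pool.size:
                used = set(pool.tolist())
                extra = [
                    int(p) for p in overflow
                    if p - 1 not in used and p + 1 not in used
                ]
                pool = np.concatenate([pool, np.array(extra, dtype=pool.dtype)])
            if cursor + k > pool.size:
                raise InfeasibleSpec("CDS too short for requested divergence")
            positions = np.sort(pool[cursor : cursor + k])
            cursor += k

            for _ in range(30):
                g = list(genome)
                _mutate_cds(rng, g, cds_start, positions.tolist())
                strain = "".join(g)
                cds = strain[cds_start : orf_end - 3]
                protein = translate(cds, _CODE4)
                if spec.ntr_indels_between_strains:
                    strain = _apply_ntr_indels(rng, strain, stop_pos, orf_end)
                new_start = strain.index(cds) if cds in strain else -1
                try:
                    if new_start < 0:
                        raise _SelfCheckFailed()
                    orf = _annotate_and_check(
                        NucSeq(id=seq_id, residues=strain), new_start, protein
                    )
                except _SelfCheckFailed:
                    continue
                break
            else:  # pragma: no cover - rejection loop exhausted
                raise InfeasibleSpec(f"could not realize strain {seq_id}")

            usage = codon_usage(cds, _CODE4, seq_id=seq_id)
            seqs.append(NucSeq(id=seq_id, residues=strain, source="synthetic"))
            truths.append(
                TruthRecord(
                    seq_id=seq_id,
                    species_id=species_id,
                    orf_start=orf.start,
                    orf_end=orf.end,
                    protein=protein,
                    trp_uga=usage.trp_uga,
                    trp_ugg=usage.trp_ugg,
                    substitution_positions=tuple(
                        int(p - cds_start) for p in positions
                    ),
                    identity_target=target,
                )
            )
    return seqs, truths


# -- degradations -------------------------------------------------------------


def inject_degradations(
    seqs: Sequence[NucSeq],
    truths: Sequence[TruthRecord],
    coverage_gaps: dict[str, tuple[int, int]] | None = None,
    truncations: dict[str, tuple[int, int]] | None = None,
    early_stops: dict[str, int] | None = None,
) -> tuple[list[NucSeq], list[TruthRecord]]:
    """Degrade named genomes: N-runs (coverage gaps), terminal truncations,
    or a premature stop substituted a given number of codons before the
    natural end of the coding region.  Truth records are refreshed by
    re-annotation of the degraded sequences.
    """
    coverage_gaps = coverage_gaps or {}
    truncations = truncations or {}
    early_stops = early_stops or {}
    truth_by_id = {t.seq_id: t for t in truths}
    for named in (*coverage_gaps, *truncations, *early_stops):
        if named not in truth_by_id:
            raise KeyError(f"unknown sequence id {named!r}")

    out_seqs: list[NucSeq] = []
    out_truths: list[TruthRecord] = []
    for seq in seqs:
        truth = truth_by_id[seq.id]
        res = seq.residues
        start, end = truth.orf_start, truth.orf_end

        if seq.id in early_stops:
            delta = early_stops[seq.id]
            n_coding = (end - start) // 3 - 1
            idx = n_coding - delta
            if not 0 < idx < n_coding:
                raise ValueError(f"early stop offset {delta} out of range")
            p = start + 3 * idx
            res = res[:p] + "UAA" + res[p + 3 :]
        if seq.id in coverage_gaps:
            gpos, glen = coverage_gaps[seq.id]
            if gpos <= start < gpos + glen or gpos <= start + 2 < gpos + glen:
                raise ValueError("coverage gap would destroy the start codon")
            res = res[:gpos] + "N" * glen + res[gpos + glen :]
        if seq.id in truncations:
            t5, t3 = truncations[seq.id]
            if t5 > start:
                raise ValueError("truncation would destroy the start codon")
            res = res[t5 : len(res) - t3 if t3 else len(res)]

        new_seq = NucSeq(id=seq.id, residues=res, source=seq.source)
        if seq.id in (*coverage_gaps, *truncations, *early_stops):
            orf = find_primary_orf(new_seq, _CODE4)
            cds = res[orf.cds[0] : orf.cds[1]]
            usage = codon_usage(cds, _CODE4, seq_id=seq.id)
            truth = dataclasses.replace(
                truth,
                orf_start=orf.start,
                orf_end=orf.end,
                protein=orf.protein,
                trp_uga=usage.trp_uga,
                trp_ugg=usage.trp_ugg,
            )
        out_seqs.append(new_seq)
        out_truths.append(truth)
    return out_seqs, out_truths


# -- mitochondrial core-gene transcripts --------------------------------------

#: protein lengths (aa) for the 12-gene core set, cox1 given as the length
#: of the GUG-extended product
CORE_GENE_LENGTHS = {
    "atp6": 251, "atp9": 74, "cob": 380, "cox1": 528, "cox2": 250,
    "cox3": 269, "nad1": 324, "nad2": 487, "nad3": 118, "nad4": 482,
    "nad5": 648, "nad6": 188,
}

#: Trp codon totals per gene; atp6/atp9/nad3 carry a single UGG (or none)
#: and never UGA, the other nine genes carry 1-5 UGAs each
_TRP_TOTALS = {
    "emuscae_like": {
        "atp6": 1, "atp9": 0, "nad3": 1, "cob": 6, "cox1": 8, "cox2": 5,
        "cox3": 6, "nad1": 6, "nad2": 7, "nad4": 7, "nad5": 9, "nad6": 4,
    },
    "heterosporus_like": {
        "atp6": 1, "atp9": 1, "nad3": 1, "cob": 7, "cox1": 9, "cox2": 6,
        "cox3": 7, "nad1": 7, "nad2": 8, "nad4": 9, "nad5": 8, "nad6": 4,
    },
}

#: UGA totals realizing the pooled Trp-UGA fractions of the two emulated
#: mitochondrial systems: 21/60 = 35% and 6/68 = 8.8%
_UGA_TOTALS = {"emuscae_like": 21, "heterosporus_like": 6}

#: first-AUG codon offset of the cox1 GUG-extended start
_COX1_EXTENSION_AA = 33


def generate_core_genes(
    seed: int, preset: str = "emuscae_like"
) -> tuple[list[NucSeq], dict[str, dict]]:
    """Generate 12 mitochondrial core-gene transcripts with a designed
    pooled Trp-UGA composition.

    The cox1 transcript is built so that its true start is an in-frame GUG
    upstream of the first AUG: the first-AUG product is 33 aa shorter than
    the 528-aa GUG-extended product.  Returns the transcripts and a
    per-gene truth table (designed Trp counts and ORF coordinates).
    """
    if preset not in _TRP_TOTALS:
        raise ValueError(f"unknown preset {preset!r}")
    trp_totals = _TRP_TOTALS[preset]
    n_uga = _UGA_TOTALS[preset]
    rng = np.random.default_rng(seed)

    # distribute the UGA total over the nine eligible genes, 1..5 each for
    # the emuscae-like preset, 0..2 for the sparse comparator
    eligible = [g for g in CORE_GENE_LENGTHS
                if g not in ("atp6", "atp9", "nad3") and trp_totals[g] > 0]
    lo, hi = (1, 5) if preset == "emuscae_like" else (0, 2)
    while True:
        alloc = {g: lo for g in eligible}
        rest = n_uga - lo * len(eligible)
        if rest < 0:
            raise ValueError("UGA total too small for allocation floor")
        for _ in range(rest):
            open_genes = [g for g in eligible
                          if alloc[g] < min(hi, trp_totals[g])]
            alloc[_pick(rng, open_genes)] += 1
        if all(alloc[g] <= trp_totals[g] for g in eligible):
            break

    seqs: list[NucSeq] = []
    truth: dict[str, dict] = {}
    for gene, full_len in CORE_GENE_LENGTHS.items():
        trp = trp_totals[gene]
        uga = alloc.get(gene, 0)
        ext = _COX1_EXTENSION_AA if gene == "cox1" else 0
        for _ in range(100):
            if gene == "cox1":
                codons = _design_cds(
                    rng, full_len, trp, uga,
                    no_aug_codons=range(1, ext + 1),
                    start_codon="GUG",
                )
                codons[ext] = "AUG"
            else:
                codons = _design_cds(rng, full_len, trp, uga)
            ntr5_len = int(rng.integers(24, 61))
            ntr5, _ = _design_ntr5(rng, ntr5_len, scrub_starts=(gene == "cox1"))
            ntr3 = _rand_nt(rng, int(rng.integers(12, 41)))
            transcript = ntr5 + "".join(codons) + ntr3
            aug_start = ntr5_len + 3 * ext
            baseline = translate(
                "".join(codons[ext:-1]), _CODE4
            )
            try:
                orf = _annotate_and_check(
                    NucSeq(id=gene, residues=transcript), aug_start, baseline
                )
            except _SelfCheckFailed:
                continue
            usage = codon_usage(transcript[orf.cds[0] : orf.cds[1]], _CODE4)
            if (usage.trp_uga, usage.trp_ugg) != (uga, trp - uga):
                continue
            break
        else:  # pragma: no cover
            raise InfeasibleSpec(f"could not realize core gene {gene}")
        seqs.append(NucSeq(id=gene, residues=transcript, source="synthetic"))
        truth[gene] = {
            "gene": gene,
            "protein_len": full_len - ext,
            "extended_protein_len": full_len if gene == "cox1" else None,
            "trp_uga": uga,
            "trp_ugg": trp - uga,
            "orf_start": orf.start,
            "orf_end": orf.end,
        }
    return seqs, truth
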
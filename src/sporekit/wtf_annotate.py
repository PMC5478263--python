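"""Sequence-feature classification of wtf-like gene families.

wtf genes are meiotic-drive genes of fission yeasts that can encode two
isoforms from one locus: a long antidote transcript from the annotated
start codon, and a shorter poison transcript initiated inside the gene.
A ~150-bp conserved element in predicted intron 1 marks genes able to make
the poison isoform, and the position of the first in-frame ATG downstream
of that element splits them into Intron-1-ATG and Exon-2-ATG subtypes.
Genes lacking the element and any early in-frame ATG are "antidote-only";
genes with inactivating lesions (lost start codon, premature stop,
frameshifting indel, segmental deletion) are pseudogenes.  The module also
computes alignment-based pairwise identity and reconstructs deletions
mediated by recombination between directly oriented LTRs.

Coordinates throughout are 1-based inclusive on the gene-forward strand of
the supplied sequence, GFF3-style.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "GeneModel",
    "MotifDefinition",
    "MotifHit",
    "AtgResult",
    "Lesion",
    "ClassificationResult",
    "FamilyStructure",
    "scan_motif",
    "locate_first_inframe_atg",
    "call_pseudogene",
    "classify_gene",
    "pairwise_identity",
    "LtrRegion",
    "LtrDeletionEvent",
    "detect_ltr_deletion",
    "infer_family_consensus",
]

GAP = "-"
STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneModel:
    """Exon/intron structure of one gene on its forward strand."""

    gene_id: str
    exons: List[Tuple[int, int]]      # 1-based inclusive, sorted
    cds_start: int                    # position of the annotated start codon
    genome_id: str = ""
    chromosome: str = ""
    strand: str = "+"

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        for (s1, e1), (s2, e2) in zip(self.exons[:-1], self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"{self.gene_id}: exon end < start")
        e1s, e1e = self.exons[0]
        if not (e1s <= self.cds_start <= e1e):
            raise ValueError(f"{self.gene_id}: cds_start outside exon 1")

    @property
    def exon2_start(self) -> int:
        if len(self.exons) < 2:
            raise ValueError(f"{self.gene_id}: gene has a single exon")
        return self.exons[1][0]

    def exon1_cds_length(self) -> int:
        return self.exons[0][1] - self.cds_start + 1

    def spliced_cds(self, sequence: str) -> str:
        parts = [sequence[self.cds_start - 1:self.exons[0][1]]]
        parts += [sequence[s - 1:e] for s, e in self.exons[1:]]
        return "".join(parts)


@dataclass
class MotifDefinition:
    motif_id: str                     # "conserved_up" | "intron1_150bp" | custom
    consensus: str
    min_identity: float = 0.8
    expected_context: str = "intron1"  # or "upstream"

    def __post_init__(self):
        if not self.consensus:
            raise ValueError("empty motif consensus")
        if self.motif_id == "conserved_up" and len(self.consensus) != 288:
            raise ValueError("conserved_up consensus must be 288 bp")
        if self.motif_id == "intron1_150bp" and len(self.consensus) != 150:
            raise ValueError("intron1_150bp consensus must be 150 bp")


@dataclass
class MotifHit:
    position: int      # 1-based start in the scanned sequence
    identity: float


def scan_motif(sequence: str, motif: MotifDefinition) -> List[MotifHit]:
    """Ungapped sliding-window identity scan; returns non-overlapping best
    hits with identity >= motif.min_identity, best-first greedy selection,
    ties resolved leftmost.  Positions are 1-based."""
    L = len(motif.consensus)
    if len(sequence) < L:
        raise ValueError("sequence shorter than motif")
    seq = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    mot = np.frombuffer(motif.consensus.upper().encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq, L)
    identity = (windows == mot).mean(axis=1)
    candidates = np.nonzero(identity >= motif.min_identity)[0]
    order = sorted(candidates, key=lambda i: (-identity[i], i))
    taken: List[int] = []
    for i in order:
        if all(abs(i - j) >= L for j in taken):
            taken.append(int(i))
    return [MotifHit(position=i + 1, identity=float(identity[i]))
            for i in sorted(taken)]


@dataclass
class AtgResult:
    location: str                 # "intron1" | "exon2" | "none"
    offset: Optional[int]         # bp before exon 2 (intron1) or into exon 2
    distance_to_exon2: Optional[int]
    in_frame: bool


def locate_first_inframe_atg(
    gene: GeneModel,
    sequence: str,
    from_position: int,
    exon2_depth_limit: int = 150,
) -> AtgResult:
    """First ATG downstream of ``from_position`` that is in frame with the
    predicted coding sequence, searching through intron 1 and the first
    ``exon2_depth_limit`` bp of exon 2.

    An intron-1 ATG is "in frame" if translation initiated there reads into
    exon 2 in the predicted CDS frame (the poison isoform begins with a few
    intron-1-coded residues); an exon-2 ATG must sit on a predicted-CDS
    codon boundary.  Out-of-frame ATGs are skipped.
    """
    e2 = gene.exon2_start
    l1 = gene.exon1_cds_length()
    if from_position > e2:
        raise ValueError(
            f"from_position {from_position} is beyond the start of exon 2 ({e2})")
    hi = min(e2 + exon2_depth_limit, len(sequence) - 2)
    for p in range(max(from_position, 1), hi + 1):
        if sequence[p - 1:p + 2].upper() != "ATG":
            continue
        if p < e2:
            in_frame = (e2 - p) % 3 == l1 % 3
            if in_frame:
                return AtgResult(location="intron1", offset=e2 - p,
                                 distance_to_exon2=e2 - p, in_frame=True)
        else:
            off = p - e2
            if off >= exon2_depth_limit:
                break
            if (l1 + off) % 3 == 0:
                return AtgResult(location="exon2", offset=off,
                                 distance_to_exon2=0, in_frame=True)
    return AtgResult(location="none", offset=None, distance_to_exon2=None,
                     in_frame=False)


@dataclass
class FamilyStructure:
    """Consensus gene structure of the family: expected per-exon CDS
    lengths and total CDS length."""
    exon_lengths: List[int]
    cds_length: int

    @property
    def exon_count(self) -> int:
        return len(self.exon_lengths)


@dataclass
class Lesion:
    kind: str      # lost_start | premature_stop | frameshift_indel | segmental_deletion
    detail: str


def call_pseudogene(
    gene: GeneModel,
    sequence: str,
    consensus: FamilyStructure,
    premature_stop_margin: float = 0.10,
    deletion_length_fraction: float = 0.50,
) -> List[Lesion]:
    """Detect pseudogenizing lesions against the family consensus
    structure.

    - lost_start: predicted CDS does not begin with ATG;
    - frameshift_indel: spliced CDS length incongruent with the consensus
      CDS length modulo 3;
    - premature_stop: an in-frame stop codon before the final
      ``premature_stop_margin`` fraction of the consensus CDS;
    - segmental_deletion: an expected exon missing, or shorter than
      ``deletion_length_fraction`` of its consensus length.
    """
    lesions: List[Lesion] = []
    cds = gene.spliced_cds(sequence).upper()
    if cds[:3] != "ATG":
        lesions.append(Lesion("lost_start", f"CDS begins with {cds[:3]}"))
    if len(cds) % 3 != consensus.cds_length % 3:
        lesions.append(Lesion(
            "frameshift_indel",
            f"spliced CDS length {len(cds)} != consensus {consensus.cds_length} mod 3"))
    cutoff = (1.0 - premature_stop_margin) * consensus.cds_length
    for ci in range(0, len(cds) - 3, 3):
        if cds[ci:ci + 3] in STOPS and ci < cutoff:
            lesions.append(Lesion(
                "premature_stop",
                f"in-frame stop at CDS position {ci + 1} of {len(cds)}"))
            break
    if len(gene.exons) < consensus.exon_count:
        lesions.append(Lesion(
            "segmental_deletion",
            f"{len(gene.exons)} exons, consensus expects {consensus.exon_count}"))
    else:
        for i, expected in enumerate(consensus.exon_lengths):
            if i >= len(gene.exons):
                break
            s, e = gene.exons[i]
            length = (e - s + 1) if i > 0 else (e - gene.cds_start + 1)
            if length < deletion_length_fraction * expected:
                lesions.append(Lesion(
                    "segmental_deletion",
                    f"exon {i + 1} length {length} < "
                    f"{deletion_length_fraction:.0%} of consensus {expected}"))
                break
    return lesions


@dataclass
class ClassificationResult:
    gene_id: str
    category: str
    reasons: List[str]
    atg_distance_to_exon2: Optional[int] = None


def classify_gene(
    gene: GeneModel,
    sequence: str,
    motifs: Mapping[str, MotifDefinition],
    consensus: FamilyStructure,
    divergent_list: Optional[Set[str]] = None,
    exon2_depth_limit: int = 150,
) -> ClassificationResult:
    """Assign one category to the gene.

    Precedence: (1) pseudogene when lesions are found; (2) member of the
    explicit divergent list; (3) intron-1 150-bp motif present ->
    poison-and-antidote, subtyped by the first in-frame ATG downstream of
    the motif; (4) no motif and no early in-frame ATG -> antidote-only;
    (5) otherwise divergent/unclassified.
    """
    reasons: List[str] = []
    lesions = call_pseudogene(gene, sequence, consensus)
    if lesions:
        reasons += [f"{l.kind}: {l.detail}" for l in lesions]
        return ClassificationResult(gene.gene_id, "pseudogene", reasons)
    if divergent_list and gene.gene_id in divergent_list:
        return ClassificationResult(gene.gene_id, "divergent_unclassified",
                                    ["listed as divergent"])
    intron1 = sequence[gene.exons[0][1]:gene.exon2_start - 1]
    intron1_offset = gene.exons[0][1]  # 0-based start of intron 1
    motif = motifs.get("intron1_150bp")
    hit = None
    if motif is not None and len(intron1) >= len(motif.consensus):
        hits = scan_motif(intron1, motif)
        hit = hits[0] if hits else None
    if hit is not None:
        reasons.append(f"intron-1 motif at {intron1_offset + hit.position} "
                       f"(identity {hit.identity:.2f})")
        scan_from = intron1_offset + hit.position + len(motif.consensus)
        atg = locate_first_inframe_atg(gene, sequence, scan_from,
                                       exon2_depth_limit)
        if atg.location == "intron1":
            reasons.append(f"first in-frame ATG in intron 1, "
                           f"{atg.distance_to_exon2} bp before exon 2")
            return ClassificationResult(gene.gene_id,
                                        "poison_and_antidote_intron1_atg",
                                        reasons, atg.distance_to_exon2)
        if atg.location == "exon2":
            reasons.append(f"first in-frame ATG {atg.offset} bp into exon 2")
            return ClassificationResult(gene.gene_id,
                                        "poison_and_antidote_exon2_atg",
                                        reasons, 0)
        reasons.append("motif present but no in-frame ATG in search window")
        return ClassificationResult(gene.gene_id, "antidote_only", reasons)
    atg = locate_first_inframe_atg(gene, sequence, intron1_offset + 1,
                                   exon2_depth_limit)
    if atg.location == "none":
        reasons.append("no intron-1 motif; no early in-frame ATG; intact CDS")
        return ClassificationResult(gene.gene_id, "antidote_only", reasons)
    reasons.append(f"early in-frame ATG ({atg.location}) without intron-1 motif")
    return ClassificationResult(gene.gene_id, "divergent_unclassified", reasons)


def pairwise_identity(aligned_a: str, aligned_b: str) -> float:
    """Fraction of identical bases over the alignment length, after
    removing columns gapped in both sequences.  A column counts as
    identical only when both characters are equal and neither is a gap."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    ident = length = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x == GAP and y == GAP:
            continue
        length += 1
        if x == y and x != GAP:
            ident += 1
    if length == 0:
        raise ValueError("alignment has no informative columns")
    return ident / length


# ----------------------------------------------------------------------
# LTR-mediated deletion detection
# ----------------------------------------------------------------------

@dataclass
class LtrRegion:
    """A genomic region with its sequence and LTR annotations
    ((start, end, strand), 1-based inclusive)."""
    sequence: str
    ltrs: List[Tuple[int, int, str]]


@dataclass
class LtrDeletionEvent:
    deleted_start: int        # donor coordinates, 1-based inclusive
    deleted_end: int
    junction_position: int    # donor coordinate of the (leftmost) junction
    homology_length: int      # maximal perfect match spanning the junction


def detect_ltr_deletion(
    donor: LtrRegion,
    recipient: LtrRegion,
) -> Tuple[Optional[LtrDeletionEvent], str]:
    """Reconstruct a deletion mediated by recombination between the donor's
    directly oriented LTR pair, given the recipient's solo LTR at the
    syntenic position.

    The recipient LTR is compared base-by-base against both donor copies:
    its maximal prefix matching copy 1 and maximal suffix matching copy 2
    bracket the recombination junction, and their overlap is the breakpoint
    homology (the stretch where the two donor copies are identical).
    Returns (event, reason); event is None when the donor lacks a directly
    oriented pair or the recipient LTR is not a clean copy1->copy2 hybrid.
    """
    if len(donor.ltrs) != 2:
        return None, f"donor has {len(donor.ltrs)} LTR annotations, need 2"
    (s1, e1, st1), (s2, e2, st2) = sorted(donor.ltrs)
    if st1 != st2:
        return None, "donor LTR pair is inverted, not directly oriented"
    if len(recipient.ltrs) != 1:
        return None, "recipient must carry a single LTR at the syntenic position"
    rs, re_, _ = recipient.ltrs[0]
    l1 = donor.sequence[s1 - 1:e1].upper()
    l2 = donor.sequence[s2 - 1:e2].upper()
    lr = recipient.sequence[rs - 1:re_].upper()
    n = min(len(l1), len(l2), len(lr))
    l1, l2, lr = l1[:n], l2[:n], lr[:n]
    p = 0
    while p < n and lr[p] == l1[p]:
        p += 1
    q = 0
    while q < n and lr[n - 1 - q] == l2[n - 1 - q]:
        q += 1
    if p + q < n:
        return None, "recipient LTR is not a clean hybrid of the donor pair"
    j = n - q     # leftmost consistent junction offset (0-based)
    homology = p + q - n
    event = LtrDeletionEvent(
        deleted_start=s1 + j,
        deleted_end=s2 + j - 1,
        junction_position=s1 + j,
        homology_length=homology,
    )
    return event, "ok"


def infer_family_consensus(
    genes: Sequence[GeneModel],
    expected_counts: Sequence[int] = (5, 6),
) -> Dict[int, FamilyStructure]:
    """Per-exon-count consensus structures: median exon lengths across the
    genes sharing that exon count (exon-1 length measured from the start
    codon)."""
    by_count: Dict[int, List[List[int]]] = {}
    for g in genes:
        lens = [(e - g.cds_start + 1) if i == 0 else (e - s + 1)
                for i, (s, e) in enumerate(g.exons)]
        by_count.setdefault(len(g.exons), []).append(lens)
    out = {}
    for count, rows in by_count.items():
        arr = np.array(rows)
        med = [int(x) for x in np.median(arr, axis=0)]
        out[count] = FamilyStructure(exon_lengths=med, cds_length=sum(med))
    return out


def pick_consensus(structures: Mapping[int, FamilyStructure],
                   gene: GeneModel) -> FamilyStructure:
    """Structure matching the gene's exon count, else the nearest (ties to
    the smaller count) — a gene with a whole exon deleted matches none."""
    n = len(gene.exons)
    if n in structures:
        return structures[n]
    best = min(structures, key=lambda c: (abs(c - n), c))
    return structures[best]
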
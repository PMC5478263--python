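"""Synthetic inputs with known ground truth for the whole pipeline.

Emulated here: segregating SNPs between two parental haplotypes, meiosis
with recombination producing tetrads, killer-dependent spore death, pooled
sequencing of viable progeny as binomial read counts at Poisson depth,
mosaic backcross genomes, and wtf-like gene families with planted motifs,
introns, LTR flanks and pseudogenizing mutations.

All generators are seeded and bitwise reproducible, and every planted
feature is reported as ground truth for downstream recovery tests.

Default regimes follow the study conditions the pipeline is meant for:
mean sequencing depth ~15x, pools of >=150 viable colonies, 40+ tetrads
per cross, SNP density 25 per 100 kb (a reduced-scale stand-in for the
~3.1 SNPs/kb divergence between fission-yeast isolates), and a
fission-yeast-like recombination rate of 0.17 cM/kb.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import drive_model
from .drive_model import CrossConfig, spore_survival_probability
from .tetrad_stats import Spore, TetradRecord

__all__ = [
    "DEFAULT_SNP_DENSITY",
    "DEFAULT_CM_PER_KB",
    "generate_snp_map",
    "simulate_meiosis_tetrads",
    "PoolSample",
    "simulate_viable_spore_pool",
    "simulate_pool_readcounts",
    "MosaicHaplotype",
    "generate_mosaic_genome",
    "simulate_mosaic_cross_pool",
    "SyntheticGenePlan",
    "SyntheticGene",
    "WtfFamily",
    "generate_wtf_family",
    "diverge_ltr_pair",
    "apply_ltr_recombination",
]

DEFAULT_SNP_DENSITY = 25 / 100_000   # SNPs per bp (25 per 100 kb)
DEFAULT_CM_PER_KB = 0.17             # fission-yeast-scale recombination rate

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}


# ----------------------------------------------------------------------
# SNP maps
# ----------------------------------------------------------------------

def generate_snp_map(
    chrom_lengths: Mapping[str, int],
    density: float = DEFAULT_SNP_DENSITY,
    seed: int = 0,
) -> pd.DataFrame:
    """Random SNP positions along each chromosome (reference allele is the
    parent1 allele).  Columns: chrom, pos (1-based), ref_base, var_base."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chrom_lengths.items():
        n = rng.poisson(density * length)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(n, length),
                                 replace=False))
        ref = rng.integers(0, 4, size=pos.size)
        alt = (ref + rng.integers(1, 4, size=pos.size)) % 4
        for p, r, a in zip(pos, ref, alt):
            rows.append((chrom, int(p), BASES[r], BASES[a]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref_base", "var_base"])


# ----------------------------------------------------------------------
# Tetrad simulation (marker-level, matching the analytic model)
# ----------------------------------------------------------------------

def simulate_meiosis_tetrads(
    config: CrossConfig, n: int, seed: int = 0
) -> List[TetradRecord]:
    """Simulate ``n`` tetrads under the cross configuration.

    Uses the same two-pair tetrad arrangement as the analytic enumeration:
    every locus segregates exactly 2:2 within each tetrad, pairs swap
    parental origin per interval with the interval's recombination
    fraction, and each spore dies independently with probability
    1 - survival.  Genotypes are recorded for all spores (ground truth).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    loci = config.loci
    fractions = np.array(config.interval_fractions())
    killers = config.present_killers()
    records = []
    for t in range(n):
        flips = (rng.random((len(fractions), 2)) < fractions[:, None]
                 if len(fractions) else np.zeros((0, 2), bool))
        o0 = o1 = 0
        genotypes = [dict() for _ in range(4)]
        for j, locus in enumerate(loci):
            if j > 0:
                o0 ^= int(flips[j - 1, 0])
                o1 ^= int(flips[j - 1, 1])
            p1a, p2a = config.parent1[locus.id], config.parent2[locus.id]
            genotypes[0][locus.id] = p2a if o0 else p1a
            genotypes[1][locus.id] = p2a if o1 else p1a
            genotypes[2][locus.id] = p1a if o0 else p2a
            genotypes[3][locus.id] = p1a if o1 else p2a
        spores = []
        for g in genotypes:
            s = spore_survival_probability(g, killers)
            spores.append(Spore(viable=bool(rng.random() < s), genotypes=dict(g)))
        records.append(TetradRecord(cross_id="sim", tetrad_id=f"t{t}", spores=spores))
    return records


# ----------------------------------------------------------------------
# Viable-spore pools and pooled read counts
# ----------------------------------------------------------------------

@dataclass
class PoolSample:
    """Genotypes of pooled viable colonies.

    ``variant_indicator[chrom]`` is an (n_colonies, n_snps) boolean array:
    True where the colony carries the variant (parent2/donor) allele at the
    SNP.  ``locus_genotypes`` keeps per-colony alleles at the config loci.
    """
    snp_map: pd.DataFrame
    variant_indicator: Dict[str, np.ndarray]
    locus_genotypes: List[Dict[str, str]]

    @property
    def n_colonies(self) -> int:
        return len(self.locus_genotypes)

    def variant_frequency(self) -> pd.DataFrame:
        parts = []
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            freq = self.variant_indicator[chrom].mean(axis=0)
            parts.append(pd.DataFrame({
                "chrom": chrom, "pos": grp["pos"].to_numpy(), "var_freq": freq}))
        return pd.concat(parts, ignore_index=True)


def _meiotic_haplotype(rng, length: int, positions: np.ndarray,
                       cm_per_kb: float) -> np.ndarray:
    """Parental origin (0/1) at each position for one random spore:
    Poisson crossovers along the chromosome, random starting phase."""
    morgans = length / 1000.0 * cm_per_kb / 100.0
    n_co = rng.poisson(morgans)
    breaks = np.sort(rng.uniform(0, length, size=n_co))
    start = int(rng.integers(0, 2))
    origins = (start + np.searchsorted(breaks, positions)) % 2
    return origins.astype(np.int8)


def simulate_viable_spore_pool(
    config: CrossConfig,
    n_colonies: int,
    seed: int = 0,
    snp_map: Optional[pd.DataFrame] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    cm_per_kb: float = DEFAULT_CM_PER_KB,
    max_attempts_factor: int = 1000,
) -> PoolSample:
    """Rejection-sample viable spores from random spore analysis until
    ``n_colonies`` are collected.

    Each candidate spore is an independent meiotic product: per chromosome,
    crossovers arrive as a Poisson process at ``cm_per_kb`` and parental
    origin alternates across them, which resolves an allele at every SNP of
    ``snp_map`` as well as at the configured loci.  The spore is accepted
    with its survival probability under the cross's killers.  Raises after
    ``max_attempts_factor * n_colonies`` failed candidates (viability 0).
    """
    rng = np.random.default_rng(seed)
    if snp_map is None:
        snp_map = pd.DataFrame(columns=["chrom", "pos", "ref_base", "var_base"])
    chroms: Dict[str, Dict[str, np.ndarray]] = {}
    all_chrom_names = list(dict.fromkeys(
        list(snp_map["chrom"]) + [l.chromosome for l in config.loci]))
    for chrom in all_chrom_names:
        snp_pos = snp_map.loc[snp_map["chrom"] == chrom, "pos"].to_numpy(float)
        loci = [l for l in config.loci if l.chromosome == chrom]
        locus_pos = np.array([l.position for l in loci], dtype=float)
        length = None
        if chrom_lengths and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            hi = max([*snp_pos, *locus_pos, 1.0])
            length = int(hi * 1.05) + 1
        chroms[chrom] = {
            "snp_pos": snp_pos,
            "locus_ids": np.array([l.id for l in loci]),
            "locus_pos": locus_pos,
            "length": np.array([length]),
        }
    killers = config.present_killers()
    indicators: Dict[str, List[np.ndarray]] = {c: [] for c in all_chrom_names}
    locus_genotypes: List[Dict[str, str]] = []
    attempts = 0
    limit = max_attempts_factor * n_colonies
    while len(locus_genotypes) < n_colonies:
        if attempts >= limit:
            raise RuntimeError(
                f"could not collect {n_colonies} viable spores in {limit} "
                "attempts; cross viability may be zero")
        attempts += 1
        spore_geno: Dict[str, str] = {}
        spore_snp: Dict[str, np.ndarray] = {}
        for chrom, info in chroms.items():
            pos = np.concatenate([info["snp_pos"], info["locus_pos"]])
            origins = _meiotic_haplotype(rng, int(info["length"][0]), pos, cm_per_kb)
            n_snp = info["snp_pos"].size
            spore_snp[chrom] = origins[:n_snp].astype(bool)
            for lid, origin in zip(info["locus_ids"], origins[n_snp:]):
                parent = config.parent2 if origin else config.parent1
                spore_geno[lid] = parent[lid]
        s = spore_survival_probability(spore_geno, killers)
        if rng.random() < s:
            locus_genotypes.append(spore_geno)
            for chrom in all_chrom_names:
                indicators[chrom].append(spore_snp[chrom])
    variant_indicator = {
        c: (np.vstack(v) if v else np.zeros((0, 0), bool))
        for c, v in indicators.items()
    }
    return PoolSample(snp_map=snp_map, variant_indicator=variant_indicator,
                      locus_genotypes=locus_genotypes)


def simulate_pool_readcounts(
    pool: PoolSample,
    snp_map: Optional[pd.DataFrame] = None,
    mean_depth: float = 15.0,
    seed: int = 0,
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """Pooled sequencing of the colonies: per SNP, depth ~ Poisson
    (``mean_depth``) and the reference-read count ~ Binomial(depth, f'),
    where f' is the pool reference frequency flipped by ``error_rate``.

    Returns an allele-count table (chrom, pos, ref, alt, ref_count,
    alt_count).
    """
    if snp_map is None:
        snp_map = pool.snp_map
    rng = np.random.default_rng(seed)
    parts = []
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        ind = pool.variant_indicator[chrom]
        ref_freq = 1.0 - ind.mean(axis=0)
        f = ref_freq * (1.0 - error_rate) + (1.0 - ref_freq) * error_rate
        depth = rng.poisson(mean_depth, size=f.size)
        ref_count = rng.binomial(depth, f)
        parts.append(pd.DataFrame({
            "chrom": chrom,
            "pos": grp["pos"].to_numpy(),
            "ref": grp["ref_base"].to_numpy(),
            "alt": grp["var_base"].to_numpy(),
            "ref_count": ref_count,
            "alt_count": depth - ref_count,
        }))
    return pd.concat(parts, ignore_index=True)


# ----------------------------------------------------------------------
# Mosaic backcross genomes
# ----------------------------------------------------------------------

@dataclass
class MosaicHaplotype:
    """A backcross-derived haplotype: donor alleles inside the listed
    segments, recipient alleles elsewhere.  Segments are the ground truth
    for segment-inference tests."""
    snp_map: pd.DataFrame
    donor_segments: List[Tuple[str, int, int]]
    is_donor: pd.Series  # aligned with snp_map rows


def generate_mosaic_genome(
    donor_segments: Sequence[Tuple[str, int, int]],
    snp_map: pd.DataFrame,
) -> MosaicHaplotype:
    """Mark each SNP as donor or recipient according to the (chrom, start,
    end) segments (1-based, inclusive); segments must be sorted and
    non-overlapping per chromosome."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in donor_segments:
        if end < start:
            raise ValueError(f"segment end < start on {chrom}: {start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, segs in by_chrom.items():
        if segs != sorted(segs):
            raise ValueError(f"segments on {chrom} not sorted")
        for (s1, e1), (s2, e2) in zip(segs[:-1], segs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping segments on {chrom}")
    is_donor = pd.Series(False, index=snp_map.index)
    for chrom, segs in by_chrom.items():
        mask = snp_map["chrom"] == chrom
        pos = snp_map.loc[mask, "pos"]
        inside = pd.Series(False, index=pos.index)
        for start, end in segs:
            inside |= (pos >= start) & (pos <= end)
        is_donor.loc[mask] = inside
    return MosaicHaplotype(snp_map=snp_map,
                           donor_segments=[tuple(s) for s in donor_segments],
                           is_donor=is_donor)


def simulate_mosaic_cross_pool(
    mosaic: MosaicHaplotype,
    n_colonies: int,
    seed: int = 0,
    cm_per_kb: float = DEFAULT_CM_PER_KB,
) -> PoolSample:
    """Pool of progeny from (reference strain) x (mosaic backcross strain)
    with no killers: SNPs outside donor segments are fixed for the
    reference allele; SNPs inside segregate through normal meiosis."""
    rng = np.random.default_rng(seed)
    snp_map = mosaic.snp_map
    indicators: Dict[str, List[np.ndarray]] = {}
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(float)
        donor = mosaic.is_donor.loc[grp.index].to_numpy()
        length = int(pos.max() * 1.05) + 1 if pos.size else 1
        rows = []
        for _ in range(n_colonies):
            origins = _meiotic_haplotype(rng, length, pos, cm_per_kb)
            # variant allele only where the mosaic parent is donor AND the
            # spore inherited the mosaic parent's strand there
            rows.append((origins.astype(bool)) & donor)
        indicators[chrom] = rows
    variant_indicator = {c: np.vstack(v) for c, v in indicators.items()}
    return PoolSample(snp_map=snp_map, variant_indicator=variant_indicator,
                      locus_genotypes=[{} for _ in range(n_colonies)])


# ----------------------------------------------------------------------
# Synthetic wtf-like gene families
# ----------------------------------------------------------------------

CONSERVED_UP_LEN = 288
INTRON1_MOTIF_LEN = 150
LTR_LEN = 300


@dataclass
class SyntheticGenePlan:
    """Blueprint for one synthetic wtf-like gene.

    planted_atg: None, ("intron1", offset_bp_before_exon2) or
    ("exon2", offset_bp_into_exon2).  planted_lesion: None | "lost_start" |
    "premature_stop" | "frameshift_indel" | "segmental_deletion".
    ltr_flanks: "none" | "single" | "directly_oriented_pair".
    """
    gene_id: str
    exon_count: int = 5
    has_conserved_up: bool = True
    has_intron1_motif: bool = False
    planted_atg: Optional[Tuple[str, int]] = None
    planted_lesion: Optional[str] = None
    ltr_flanks: str = "none"

    def __post_init__(self):
        if self.exon_count not in (5, 6):
            raise ValueError("exon_count must be 5 or 6")
        if self.planted_atg is not None:
            where, off = self.planted_atg
            if where not in ("intron1", "exon2") or off < 0:
                raise ValueError(f"bad planted_atg {self.planted_atg}")
        if self.planted_lesion not in (None, "lost_start", "premature_stop",
                                       "frameshift_indel", "segmental_deletion"):
            raise ValueError(f"bad planted_lesion {self.planted_lesion}")
        if self.ltr_flanks not in ("none", "single", "directly_oriented_pair"):
            raise ValueError(f"bad ltr_flanks {self.ltr_flanks}")
        if self.planted_atg is not None and not self.has_intron1_motif:
            raise ValueError("planted_atg requires has_intron1_motif")


@dataclass
class SyntheticGene:
    gene_id: str
    sequence: str
    exons: List[Tuple[int, int]]          # 1-based inclusive, gene-forward
    cds_start: int                        # 1-based position of start codon
    ltrs: List[Tuple[int, int, str]]      # (start, end, strand)
    motif_positions: Dict[str, int]       # motif id -> 1-based start
    truth: Dict[str, object]              # planted features, exact coordinates


@dataclass
class WtfFamily:
    genes: List[SyntheticGene]
    conserved_up: str
    intron1_motif: str
    ltr: str
    consensus_structures: Dict[int, Dict[str, object]]  # exon count -> struct

    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        records = [SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
                   for g in self.genes]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\tsporekit\tgene\t1\t{len(g.sequence)}\t.\t+\t.\t"
                         f"ID={g.gene_id}\n")
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(f"{g.gene_id}\tsporekit\texon\t{s}\t{e}\t.\t+\t.\t"
                             f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n")
                fh.write(f"{g.gene_id}\tsporekit\tstart_codon\t{g.cds_start}\t"
                         f"{g.cds_start + 2}\t.\t+\t.\tParent={g.gene_id}\n")
                for i, (s, e, strand) in enumerate(g.ltrs, 1):
                    fh.write(f"{g.gene_id}\tsporekit\tlong_terminal_repeat\t{s}\t{e}"
                             f"\t.\t{strand}\t.\tID={g.gene_id}.ltr{i}\n")

    def write_truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({g.gene_id: g.truth for g in self.genes}, fh, indent=1,
                      default=str)


def _random_seq(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng, n_codons: int) -> str:
    """ATG + random internal codons without stops + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in STOPS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _mutate(rng, seq: str, rate: float, protect: Optional[set] = None) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        if protect and i in protect:
            continue
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


# exon lengths (bp of CDS per exon) for the 5- and 6-exon family layouts;
# totals are multiples of 3 so intact genes translate cleanly
_EXON_LAYOUTS = {
    5: [99, 201, 150, 120, 180],
    6: [99, 201, 150, 120, 120, 60],
}
_INTRON_LEN = 120
_INTRON1_LEN = 300


def _frame_repair_window(seq: List[str], e2_start0: int, l1: int,
                         lo: int, hi: int, keep: Optional[int]) -> None:
    """Remove in-frame ATGs in seq[lo:hi) (0-based, hi exclusive) except at
    ``keep``; in-frame is judged relative to the exon-2 reading frame."""
    for p in range(lo, min(hi, len(seq) - 2)):
        if keep is not None and p == keep:
            continue
        if seq[p] == "A" and seq[p + 1] == "T" and seq[p + 2] == "G":
            if p < e2_start0:
                in_frame = (e2_start0 - p) % 3 == l1 % 3
            else:
                in_frame = (l1 + (p - e2_start0)) % 3 == 0
            if in_frame:
                seq[p + 2] = "C"   # ATG -> ATC; cannot create a stop codon


def generate_wtf_family(
    plans: Sequence[SyntheticGenePlan],
    seed: int = 0,
    divergence: float = 0.03,
    motif_divergence: float = 0.04,
) -> WtfFamily:
    """Generate a family of wtf-like genes from per-gene blueprints.

    Family-level consensus elements (288-bp upstream element, 150-bp
    intron-1 motif, 300-bp LTR) are drawn once per family; each gene is
    point-mutated at ``divergence`` (``motif_divergence`` inside motifs).
    Splice sites, start/stop codons, planted ATGs and the in-frame-ATG
    search window are repaired after mutation so that planted ground truth
    holds exactly by construction.
    """
    rng = np.random.default_rng(seed)
    conserved_up = _random_seq(rng, CONSERVED_UP_LEN)
    intron1_motif = _random_seq(rng, INTRON1_MOTIF_LEN)
    ltr = _random_seq(rng, LTR_LEN)
    genes = []
    for plan in plans:
        genes.append(_build_gene(plan, rng, conserved_up, intron1_motif, ltr,
                                 divergence, motif_divergence))
    consensus = {
        n: {"exon_lengths": list(lens), "cds_length": sum(lens)}
        for n, lens in _EXON_LAYOUTS.items()
    }
    return WtfFamily(genes=genes, conserved_up=conserved_up,
                     intron1_motif=intron1_motif, ltr=ltr,
                     consensus_structures=consensus)


def _build_gene(plan: SyntheticGenePlan, rng, conserved_up: str,
                intron1_motif: str, ltr: str, divergence: float,
                motif_divergence: float) -> SyntheticGene:
    exon_lens = list(_EXON_LAYOUTS[plan.exon_count])
    # keep the planted ATG in frame with the downstream CDS: an intron-1 ATG
    # at offset o before exon 2 is in frame iff o ≡ L1 (mod 3); an exon-2
    # ATG at offset o iff L1 + o ≡ 0 (mod 3).  Adjust exon-1 length.
    l1 = exon_lens[0]
    if plan.planted_atg is not None:
        where, off = plan.planted_atg
        if where == "intron1":
            l1 += (off - l1) % 3
        else:
            l1 += (-(l1 + off)) % 3
        exon_lens[0] = l1
        # keep total CDS a multiple of 3
        exon_lens[-1] += (-sum(exon_lens)) % 3

    cds = _random_cds(rng, sum(exon_lens) // 3)
    exon_seqs = []
    offset = 0
    for L in exon_lens:
        exon_seqs.append(cds[offset:offset + L])
        offset += L

    intron_seqs = []
    for i in range(plan.exon_count - 1):
        if i == 0:
            inner = _random_seq(rng, _INTRON1_LEN - 4)
            intron_seqs.append("GT" + inner + "AG")
        else:
            intron_seqs.append("GT" + _random_seq(rng, _INTRON_LEN - 4) + "AG")

    flank5 = _random_seq(rng, 150)
    flank3 = _random_seq(rng, 150)
    gap_ltr = _random_seq(rng, 60)
    gap_up = _random_seq(rng, 40)

    parts: List[Tuple[str, str]] = [("flank5", flank5)]
    if plan.ltr_flanks in ("single", "directly_oriented_pair"):
        parts.append(("ltr1", ltr))
        parts.append(("gap_ltr1", gap_ltr))
    if plan.has_conserved_up:
        parts.append(("conserved_up", conserved_up))
        parts.append(("gap_up", gap_up))
    for i in range(plan.exon_count):
        parts.append((f"exon{i + 1}", exon_seqs[i]))
        if i < plan.exon_count - 1:
            parts.append((f"intron{i + 1}", intron_seqs[i]))
    if plan.ltr_flanks == "directly_oriented_pair":
        parts.append(("gap_ltr2", _random_seq(rng, 60)))
        parts.append(("ltr2", ltr))
    parts.append(("flank3", flank3))

    # assemble, remembering 0-based start of each part
    starts: Dict[str, int] = {}
    seq_chunks = []
    pos = 0
    for name, chunk in parts:
        starts[name] = pos
        seq_chunks.append(chunk)
        pos += len(chunk)
    seq = "".join(seq_chunks)
    part_len = {name: len(chunk) for name, chunk in parts}

    # plant the intron-1 motif: place it in intron 1 such that its end
    # leaves room for the ATG search region (ends 60 bp before exon 2)
    motif_positions: Dict[str, int] = {}
    seq_list = list(seq)
    intron1_start0 = starts["intron1"]
    intron1_len = part_len["intron1"]
    e2_start0 = starts["exon2"]
    if plan.has_intron1_motif:
        m0 = intron1_start0 + intron1_len - INTRON1_MOTIF_LEN - 60
        seq_list[m0:m0 + INTRON1_MOTIF_LEN] = list(intron1_motif)
        motif_positions["intron1_150bp"] = m0 + 1
    if plan.has_conserved_up:
        motif_positions["conserved_up"] = starts["conserved_up"] + 1

    # divergence: mutate everywhere, then repair constrained features
    protect = set()
    if plan.has_intron1_motif:
        m0 = motif_positions["intron1_150bp"] - 1
        protect.update(range(m0, m0 + INTRON1_MOTIF_LEN))
    if plan.has_conserved_up:
        c0 = motif_positions["conserved_up"] - 1
        protect.update(range(c0, c0 + CONSERVED_UP_LEN))
    mutated = list(_mutate(rng, "".join(seq_list), divergence, protect=protect))
    # motifs diverge at their own (lower) rate
    for mid, mstart in motif_positions.items():
        consensus = intron1_motif if mid == "intron1_150bp" else conserved_up
        div = _mutate(rng, consensus, motif_divergence)
        mutated[mstart - 1:mstart - 1 + len(div)] = list(div)
    seq_list = mutated

    exon_bounds0: List[Tuple[int, int]] = []   # 0-based [start, end)
    for i in range(plan.exon_count):
        s0 = starts[f"exon{i + 1}"]
        exon_bounds0.append((s0, s0 + exon_lens[i]))

    # repairs: start codon, splice sites, internal stops, final stop
    cds_start0 = exon_bounds0[0][0]
    seq_list[cds_start0:cds_start0 + 3] = list("ATG")
    for i in range(plan.exon_count - 1):
        i0 = starts[f"intron{i + 1}"]
        ilen = part_len[f"intron{i + 1}"]
        seq_list[i0:i0 + 2] = list("GT")
        seq_list[i0 + ilen - 2:i0 + ilen] = list("AG")
    # remove in-frame stops in the spliced CDS except the terminal one
    def spliced() -> str:
        return "".join("".join(seq_list[s:e]) for s, e in exon_bounds0)
    sp = spliced()
    exon_of = []  # map spliced index -> genomic index
    for s, e in exon_bounds0:
        exon_of.extend(range(s, e))
    for ci in range(0, len(sp) - 3, 3):
        if sp[ci:ci + 3] in STOPS:
            gi = exon_of[ci]            # T of the stop codon is at ci+1
            seq_list[exon_of[ci + 1]] = "C"   # TAA/TAG/TGA -> TCA/... no stop
            sp = spliced()
    seq_list[exon_of[len(sp) - 3]:exon_of[len(sp) - 3] + 3] = list("TAA")
    sp = spliced()
    assert sp[-3:] == "TAA" and sp[:3] == "ATG"

    # ATG search window: from intron-1 start (or motif end) to 150 bp into
    # exon 2 — clear stray in-frame ATGs, then plant the requested one
    win_lo = intron1_start0
    win_hi = e2_start0 + 150 + 3
    planted_pos0 = None
    if plan.planted_atg is not None:
        where, off = plan.planted_atg
        planted_pos0 = (e2_start0 - off) if where == "intron1" else (e2_start0 + off)
    _frame_repair_window(seq_list, e2_start0, exon_lens[0], win_lo, win_hi,
                         keep=planted_pos0)
    if planted_pos0 is not None:
        seq_list[planted_pos0:planted_pos0 + 3] = list("ATG")
        # planting inside exon 2 may have created an in-frame stop later if
        # it overwrote CDS bases; re-run the stop repair
        sp = spliced()
        for ci in range(0, len(sp) - 3, 3):
            if sp[ci:ci + 3] in STOPS:
                seq_list[exon_of[ci + 1]] = "C"
                sp = spliced()

    truth: Dict[str, object] = {
        "category": None,
        "exon_count": plan.exon_count,
        "has_conserved_up": plan.has_conserved_up,
        "has_intron1_motif": plan.has_intron1_motif,
        "planted_atg": plan.planted_atg,
        "planted_lesion": plan.planted_lesion,
        "ltr_flanks": plan.ltr_flanks,
    }
    if planted_pos0 is not None:
        truth["atg_position"] = planted_pos0 + 1

    # lesions (applied last so repairs do not undo them)
    lesion = plan.planted_lesion
    if lesion == "lost_start":
        seq_list[cds_start0 + 2] = "A"   # ATG -> ATA
    elif lesion == "premature_stop":
        n_codons = len(sp) // 3
        target = (n_codons // 2) * 3     # mid-CDS, well before the final 10%
        gi = exon_of[target]
        # codon may span a splice junction only at exon borders; layouts
        # keep codons within exons for these positions
        seq_list[exon_of[target]] = "T"
        seq_list[exon_of[target + 1]] = "A"
        seq_list[exon_of[target + 2]] = "A"
        truth["lesion_codon_index"] = target // 3
    elif lesion == "frameshift_indel":
        s0, e0 = exon_bounds0[2]
        del_pos = (s0 + e0) // 2
        del seq_list[del_pos]
        truth["lesion_position"] = del_pos + 1
        exon_bounds0 = [(s, e) if e <= del_pos else
                        ((s, e - 1) if s <= del_pos else (s - 1, e - 1))
                        for s, e in exon_bounds0]
    elif lesion == "segmental_deletion":
        # drop exon 4 and its downstream intron entirely
        idx = 3
        s0, _ = exon_bounds0[idx]
        i0 = starts[f"intron{idx + 1}"]
        ilen = part_len[f"intron{idx + 1}"]
        del_from, del_to = s0, i0 + ilen
        del seq_list[del_from:del_to]
        shift = del_to - del_from
        new_bounds = []
        for j, (s, e) in enumerate(exon_bounds0):
            if j == idx:
                continue
            if s >= del_to:
                new_bounds.append((s - shift, e - shift))
            else:
                new_bounds.append((s, e))
        exon_bounds0 = new_bounds
        truth["deleted_exon"] = idx + 1

    sequence = "".join(seq_list)
    ltrs: List[Tuple[int, int, str]] = []
    if plan.ltr_flanks in ("single", "directly_oriented_pair"):
        ltrs.append((starts["ltr1"] + 1, starts["ltr1"] + LTR_LEN, "+"))
    if plan.ltr_flanks == "directly_oriented_pair":
        l2_start0 = starts["ltr2"]
        if lesion == "frameshift_indel" and l2_start0 > truth.get("lesion_position", 0):
            l2_start0 -= 1
        if lesion == "segmental_deletion":
            l2_start0 -= (del_to - del_from)
        ltrs.append((l2_start0 + 1, l2_start0 + LTR_LEN, "+"))

    exons_1based = [(s + 1, e) for s, e in exon_bounds0]
    return SyntheticGene(
        gene_id=plan.gene_id,
        sequence=sequence,
        exons=exons_1based,
        cds_start=cds_start0 + 1,
        ltrs=ltrs,
        motif_positions=motif_positions,
        truth=truth,
    )


# ----------------------------------------------------------------------
# LTR divergence and recombination (string surgery with exact truth)
# ----------------------------------------------------------------------

def diverge_ltr_pair(
    gene: SyntheticGene,
    rate: float,
    identical_window: Tuple[int, int],
    seed: int = 0,
) -> SyntheticGene:
    """Mutate the second LTR copy of a directly oriented pair at ``rate``
    while keeping ``identical_window`` = (offset0, length) bitwise equal to
    the first copy and forcing mismatches at both window flanks, so the
    breakpoint homology of a recombination through the window is exactly
    ``length``."""
    if len(gene.ltrs) != 2:
        raise ValueError("gene does not carry an LTR pair")
    rng = np.random.default_rng(seed)
    off, length = identical_window
    (s1, e1, st1), (s2, e2, st2) = gene.ltrs
    seq = list(gene.sequence)
    l1 = gene.sequence[s1 - 1:e1]
    l2 = list(_mutate(rng, l1, rate))
    l2[off:off + length] = list(l1[off:off + length])
    for flank in (off - 1, off + length):
        if 0 <= flank < len(l1):
            choices = [b for b in "ACGT" if b != l1[flank]]
            l2[flank] = choices[int(rng.integers(0, 3))]
    seq[s2 - 1:e2] = l2
    out = SyntheticGene(gene_id=gene.gene_id, sequence="".join(seq),
                        exons=list(gene.exons), cds_start=gene.cds_start,
                        ltrs=list(gene.ltrs),
                        motif_positions=dict(gene.motif_positions),
                        truth=dict(gene.truth))
    out.truth["ltr_identical_window"] = (off, length)
    return out


def apply_ltr_recombination(gene: SyntheticGene,
                            junction_offset: Optional[int] = None) -> Dict[str, object]:
    """Homologous recombination between a directly oriented LTR pair,
    deleting the intervening segment and leaving a solo (possibly hybrid)
    LTR.

    ``junction_offset`` is the 0-based offset within the LTR at which the
    product switches from copy 1 to copy 2; defaults to the start of the
    recorded identical window (or 0 for identical copies).  Returns the
    product sequence, its solo-LTR annotation, and the ground-truth deleted
    interval in donor coordinates (1-based inclusive, leftmost-canonical).
    """
    if len(gene.ltrs) != 2:
        raise ValueError("gene does not carry an LTR pair")
    (s1, e1, st1), (s2, e2, st2) = gene.ltrs
    if st1 != st2:
        raise ValueError("LTR pair is not directly oriented")
    if junction_offset is None:
        win = gene.truth.get("ltr_identical_window")
        junction_offset = win[0] if win else 0
    j = junction_offset
    seq = gene.sequence
    product = seq[:s1 - 1 + j] + seq[s2 - 1 + j:]
    deleted_start = s1 + j          # 1-based, first deleted base
    deleted_end = s2 + j - 1        # 1-based, last deleted base
    return {
        "sequence": product,
        "solo_ltr": (s1, s1 + (e1 - s1), st1),
        "deleted_interval": (deleted_start, deleted_end),
        "junction_offset": j,
    }
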
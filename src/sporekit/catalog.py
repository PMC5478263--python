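"""Published composition of the wtf gene family in the fission-yeast
reference genome and the CBS5557 isolate.

These are the headline counts and gene lists reported for the two
genomes: how many wtf-gene locations each genome has and how large the
gene cluster at each location is (singleton/pair/triplet), which genes
carry the 150-bp intron-1 element and their poison-isoform subtype, which
genes carry pseudogenizing lesions, and which are too divergent to call.
The module exposes the raw breakdowns plus derived totals, so consistency
of the published arithmetic (e.g. 15 singletons + 5 tandem pairs = 25
genes) can be checked computationally.

CBS5557 wtf genes are named cw<N> after their syntenic reference gene
wtf<N>; suffixes a/b distinguish tandem duplicates, cw11x an extra gene
inside the cw11-cw12 cluster, and cw26/cw27/cw28 occupy locations with no
reference counterpart.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

__all__ = [
    "CLUSTER_COMPOSITION",
    "INTRON1_ATG_GENES",
    "EXON2_ATG_GENES",
    "PSEUDOGENE_LESIONS",
    "DIVERGENT_GENES",
    "NEIGHBOR_PAIR_COUNTS",
    "gene_counts",
    "poison_antidote_counts",
]

# (genome component, cluster size, number of locations with that size)
CLUSTER_COMPOSITION: List[Tuple[str, int, int]] = [
    ("reference", 1, 15),        # 15 singleton locations
    ("reference", 2, 5),         # 5 tandem-pair locations
    ("cbs5557_shared", 1, 12),   # the same 20 locations in CBS5557
    ("cbs5557_shared", 2, 7),
    ("cbs5557_shared", 3, 1),
    ("cbs5557_new", 1, 3),       # cw26, cw27, cw28
]

# the 12 genes carrying the 150-bp intron-1 element, by subtype
INTRON1_ATG_GENES = ["wtf4", "wtf13", "cw4", "cw18", "cw23"]
EXON2_ATG_GENES = ["wtf19", "wtf23", "cw8a", "cw9", "cw21", "cw22", "cw27"]

# genes with pseudogenizing lesions, by lesion class
PSEUDOGENE_LESIONS: Dict[str, List[str]] = {
    "lost_start": ["wtf3", "cw3"],
    "premature_stop": ["wtf1", "wtf12", "cw12", "cw16"],
    "frameshift_indel": ["wtf6", "wtf8", "wtf22", "wtf24"],
    "segmental_deletion": ["wtf2", "wtf17"],
}

# the eight most divergent family members (unclassifiable subtype)
DIVERGENT_GENES = ["wtf7", "cw7", "wtf11", "cw11", "wtf14", "cw14",
                   "wtf15", "cw15"]

# phylogenetic neighbor pairs at >= 95% support: syntenic vs non-syntenic
NEIGHBOR_PAIR_COUNTS = {"syntenic": 11, "non_syntenic": 5}


def gene_counts() -> Dict[str, int]:
    """Gene totals per genome derived from the cluster composition."""
    totals: Dict[str, int] = {}
    for component, size, n_locations in CLUSTER_COMPOSITION:
        genome = "reference" if component == "reference" else "cbs5557"
        totals[genome] = totals.get(genome, 0) + size * n_locations
    totals["total"] = totals["reference"] + totals["cbs5557"]
    return totals


def poison_antidote_counts() -> Dict[str, int]:
    """Counts of motif-carrying genes by poison-isoform subtype."""
    return {
        "intron1_atg": len(INTRON1_ATG_GENES),
        "exon2_atg": len(EXON2_ATG_GENES),
        "total": len(INTRON1_ATG_GENES) + len(EXON2_ATG_GENES),
    }
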
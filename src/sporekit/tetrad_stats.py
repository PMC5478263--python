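"""Viability summaries and exact tests for tetrad dissection data.

A tetrad is the four haploid spores of one meiosis; dissection records each
spore's viability and (usually for viable spores only) its genotype at
scored markers.  A heterozygous spore killer shows up here as genotype-
biased spore death: among viable spores the killer allele exceeds the
Mendelian 50%, which the exact binomial goodness-of-fit test quantifies,
while viability differences between crosses are compared with Fisher's
exact test.

Both tests use the two-sided "method of small p-values": the p-value sums
the probabilities of all outcomes no more probable than the observed one,
with a relative tie tolerance of 1e-7 to absorb floating-point equality.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Spore",
    "TetradRecord",
    "ViabilitySummary",
    "RatioTestResult",
    "summarize_viability",
    "fisher_exact_2x2",
    "exact_binomial_two_sided",
    "genotype_ratio_test",
    "read_tetrad_table",
    "write_tetrad_table",
]

TIE_REL_TOL = 1e-7
MISSING = "."


@dataclass
class Spore:
    viable: bool
    genotypes: Dict[str, str] = field(default_factory=dict)


@dataclass
class TetradRecord:
    cross_id: str
    tetrad_id: str
    spores: List[Spore]

    def __post_init__(self):
        if len(self.spores) != 4:
            raise ValueError(
                f"tetrad {self.tetrad_id}: expected 4 spores, got {len(self.spores)}")


@dataclass
class ViabilitySummary:
    viable: int
    total: int
    fraction: float
    per_genotype: Dict[str, Dict[str, Tuple[int, int, float]]]
    histogram: List[int]  # index = viable spores per tetrad (0..4)


def summarize_viability(records: Sequence[TetradRecord]) -> ViabilitySummary:
    """Overall and per-genotype viability plus the viable-per-tetrad
    histogram.  Per-genotype counts include only genotyped spores."""
    if not records:
        raise ValueError("no tetrad records")
    viable = total = 0
    hist = [0] * 5
    per: Dict[str, Dict[str, List[int]]] = {}
    for rec in records:
        v = sum(1 for s in rec.spores if s.viable)
        hist[v] += 1
        viable += v
        total += 4
        for s in rec.spores:
            for locus, allele in s.genotypes.items():
                cell = per.setdefault(locus, {}).setdefault(allele, [0, 0])
                cell[1] += 1
                if s.viable:
                    cell[0] += 1
    per_genotype = {
        locus: {allele: (v, n, v / n) for allele, (v, n) in alleles.items()}
        for locus, alleles in per.items()
    }
    return ViabilitySummary(viable=viable, total=total, fraction=viable / total,
                            per_genotype=per_genotype, histogram=hist)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is <= that of the observed table (relative
    tie tolerance 1e-7).  Degenerate margins give p = 1 with a warning.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 margin; Fisher p set to 1")
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    include = pmf <= p_obs * (1.0 + TIE_REL_TOL)
    if include.all():
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact binomial goodness-of-fit p-value (two-sided, method of small
    p-values): sum of P(j; n, p0) over all j whose point probability does
    not exceed the observed one (relative tie tolerance 1e-7)."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"null probability must be in (0,1), got {p0}")
    support = np.arange(0, n + 1)
    pmf = stats.binom.pmf(support, n, p0)
    p_obs = pmf[k]
    include = pmf <= p_obs * (1.0 + TIE_REL_TOL)
    if include.all():
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


@dataclass
class RatioTestResult:
    locus: str
    allele: str
    among: str
    k: int
    n: int
    p_value: float
    inferred: int  # spores whose genotype came from 2:2 tetrad completion


def _complete_genotypes(rec: TetradRecord, locus: str) -> Tuple[List[Optional[str]], int]:
    """Genotypes of the four spores at ``locus``; if exactly one spore is
    untyped and the other three are typed, fill it by 2:2 completion."""
    alleles: List[Optional[str]] = [s.genotypes.get(locus) for s in rec.spores]
    inferred = 0
    typed = [a for a in alleles if a is not None]
    if len(typed) == 3 and len(set(typed)) == 2:
        counts = Counter(typed)
        missing_allele = min(counts, key=lambda a: (counts[a], a))
        if counts[missing_allele] == 1:
            idx = alleles.index(None)
            alleles[idx] = missing_allele
            inferred = 1
    return alleles, inferred


def genotype_ratio_test(
    records: Sequence[TetradRecord],
    locus: str,
    allele: str,
    among: str = "viable",
    infer_missing: bool = True,
) -> RatioTestResult:
    """Test whether the focal ``allele`` deviates from 50% among spores of
    the selected class (``viable``, ``dead`` or ``all``), using the exact
    binomial test.

    Dead spores often lack genotypes; when ``infer_missing`` and exactly
    three spores of a tetrad are typed at the locus, the fourth is
    completed assuming 2:2 segregation and counted as inferred.
    """
    if among not in ("viable", "dead", "all"):
        raise ValueError(f"among must be viable|dead|all, got {among!r}")
    k = n = inferred_total = 0
    for rec in records:
        if infer_missing:
            alleles, inf = _complete_genotypes(rec, locus)
        else:
            alleles, inf = [s.genotypes.get(locus) for s in rec.spores], 0
        used_inferred = False
        for spore, a in zip(rec.spores, alleles):
            if a is None:
                continue
            if among == "viable" and not spore.viable:
                continue
            if among == "dead" and spore.viable:
                continue
            n += 1
            if a == allele:
                k += 1
            if inf and spore.genotypes.get(locus) is None:
                used_inferred = True
        if used_inferred:
            inferred_total += 1
    if n == 0:
        raise ValueError(f"no genotyped spores at {locus} among {among}")
    p = exact_binomial_two_sided(k, n, 0.5)
    return RatioTestResult(locus=locus, allele=allele, among=among,
                           k=k, n=n, p_value=p, inferred=inferred_total)


# ----------------------------------------------------------------------
# TSV round-trip: cross_id, tetrad_id, spore_index (1-4), viable {0,1},
# one column per marker, "." for missing.
# ----------------------------------------------------------------------

def read_tetrad_table(path) -> List[TetradRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["cross_id", "tetrad_id", "spore_index", "viable"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"tetrad table missing columns: {missing}")
    markers = [c for c in df.columns if c not in required]
    records: List[TetradRecord] = []
    for (cross, tet), grp in df.groupby(["cross_id", "tetrad_id"], sort=False):
        grp = grp.sort_values("spore_index")
        if list(grp["spore_index"].astype(int)) != [1, 2, 3, 4]:
            raise ValueError(f"tetrad {tet}: spore_index must be 1..4")
        spores = []
        for _, row in grp.iterrows():
            genotypes = {m: row[m] for m in markers
                         if isinstance(row[m], str) and row[m] != MISSING}
            spores.append(Spore(viable=bool(int(row["viable"])), genotypes=genotypes))
        records.append(TetradRecord(cross_id=str(cross), tetrad_id=str(tet),
                                    spores=spores))
    return records


def write_tetrad_table(records: Sequence[TetradRecord], path) -> None:
    markers = sorted({l for r in records for s in r.spores for l in s.genotypes})
    rows = []
    for rec in records:
        for i, s in enumerate(rec.spores, start=1):
            row = {"cross_id": rec.cross_id, "tetrad_id": rec.tetrad_id,
                   "spore_index": i, "viable": int(s.viable)}
            for m in markers:
                row[m] = s.genotypes.get(m, MISSING)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
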
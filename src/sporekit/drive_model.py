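"""Analytic poison-antidote model of spore killing in fungal crosses.

A spore killer ("wtf"-like) allele expresses a trans-acting poison that
harms every spore of the ascus and a cis-restricted antidote that rescues
only spores inheriting the killer.  Each killer allele is parameterized by
a killing penetrance ``kappa`` (probability that an unprotected spore
exposed to the poison dies) and an antidote efficiency ``pi`` (probability
that a spore carrying a protective allele is rescued).  A ``resistance_set``
records which poisons an allele's antidote neutralizes; by default an
allele only protects against its own poison, so two distinct killers in the
same cross kill each other's spores mutually.

The module provides exact expectations under a cross configuration
(tetrad viable-count distribution, spore viability, allele frequency among
surviving spores) by enumerating tetrad segregation patterns, plus a
deterministic maximum-likelihood fitter for (kappa, pi) from dissection
data.

Tetrad segregation model
------------------------
Each locus segregates 2:2 within the tetrad (no gene conversion).  The four
spores are organised as two fixed pairs, each pair containing one spore of
either parental origin; for every interval between adjacent loci each pair
independently swaps parental origin with probability equal to the interval's
recombination fraction.  This "independent per-interval arrangement"
reproduces the per-spore recombinant fraction exactly and keeps enumeration
closed-form; it is not a full four-strand chiasma model (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import optimize

__all__ = [
    "KillerAllele",
    "Locus",
    "CrossConfig",
    "KILLER_PRESETS",
    "haldane_fraction",
    "cross_config_from_dict",
    "load_cross_config",
    "save_cross_config",
    "spore_survival_probability",
    "enumerate_tetrad_patterns",
    "tetrad_outcome_distribution",
    "expected_viability",
    "expected_viable_allele_frequency",
    "FitResult",
    "fit_killer_parameters",
]


# Truncation-construct presets: Ta keeps full killing and protection; Tb/Te
# retain killing but have weakened protection (Te weaker than Tb); Tc behaves
# like Ta; Td has lost killing but protects fully.  The partial-protection
# values for Tb/Te are model placeholders on the qualitative ordering
# pi(Ta) > pi(Tb) > pi(Te); only the ordering is constrained by phenotype.
KILLER_PRESETS: Dict[str, Tuple[float, float]] = {
    "Ta": (1.0, 1.0),
    "Tb": (1.0, 0.7),
    "Tc": (1.0, 1.0),
    "Td": (0.0, 1.0),
    "Te": (1.0, 0.4),
}


def haldane_fraction(distance_bp: float, cm_per_kb: float = 0.17) -> float:
    """Map a physical distance to a recombination fraction (Haldane, no
    interference).  ``cm_per_kb`` defaults to a fission-yeast-like 0.17."""
    morgans = distance_bp / 1000.0 * cm_per_kb / 100.0
    return 0.5 * (1.0 - math.exp(-2.0 * morgans))


@dataclass(frozen=True)
class KillerAllele:
    """A killer (or killer-derived) allele at a single locus."""

    id: str
    locus: str
    kappa: float
    pi: float
    resistance_set: frozenset = None  # type: ignore[assignment]

    def __post_init__(self):
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError(f"kappa must be in [0,1], got {self.kappa}")
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError(f"pi must be in [0,1], got {self.pi}")
        if self.resistance_set is None:
            object.__setattr__(self, "resistance_set", frozenset({self.id}))
        else:
            object.__setattr__(self, "resistance_set", frozenset(self.resistance_set))

    @classmethod
    def from_preset(cls, id: str, locus: str, preset: str,
                    resistance_set: Optional[Iterable[str]] = None) -> "KillerAllele":
        kappa, pi = KILLER_PRESETS[preset]
        return cls(id=id, locus=locus, kappa=kappa, pi=pi,
                   resistance_set=frozenset(resistance_set) if resistance_set else None)


@dataclass(frozen=True)
class Locus:
    """A genetic locus; ``recomb_fraction_to_next`` links it to the next
    locus on the same chromosome (ignored for the last locus of a
    chromosome; loci on different chromosomes assort independently)."""

    id: str
    chromosome: str
    position: int
    recomb_fraction_to_next: Optional[float] = None

    def __post_init__(self):
        r = self.recomb_fraction_to_next
        if r is not None and not (0.0 <= r <= 0.5):
            raise ValueError(f"recombination fraction must be in [0,0.5], got {r}")


@dataclass
class CrossConfig:
    """A diploid cross: ordered loci, two haploid parental genotypes, and
    the killer alleles segregating in it."""

    loci: List[Locus]
    parent1: Dict[str, str]
    parent2: Dict[str, str]
    killers: List[KillerAllele] = field(default_factory=list)

    def __post_init__(self):
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")
        by_chrom: Dict[str, List[Locus]] = {}
        for l in self.loci:
            by_chrom.setdefault(l.chromosome, []).append(l)
        for chrom, ls in by_chrom.items():
            pos = [l.position for l in ls]
            if pos != sorted(pos):
                raise ValueError(f"loci on {chrom} not sorted by position")
        for parent, name in ((self.parent1, "parent1"), (self.parent2, "parent2")):
            missing = set(ids) - set(parent)
            if missing:
                raise ValueError(f"{name} missing alleles at loci: {sorted(missing)}")
        for k in self.killers:
            if k.locus not in ids:
                raise ValueError(f"killer {k.id}: locus {k.locus} not in loci")
            if self.parent1.get(k.locus) != k.id and self.parent2.get(k.locus) != k.id:
                raise ValueError(
                    f"killer {k.id} not carried by either parent at locus {k.locus}")

    # -- helpers ---------------------------------------------------------
    def allele_registry(self) -> Dict[str, KillerAllele]:
        return {k.id: k for k in self.killers}

    def present_killers(self) -> List[KillerAllele]:
        """Killers whose poison is expressed in this diploid (carried by at
        least one parent; validation guarantees all of them)."""
        return list(self.killers)

    def interval_fractions(self) -> List[float]:
        """Recombination fraction between each consecutive pair of loci in
        order; 0.5 across chromosome boundaries or when unspecified."""
        fractions = []
        for a, b in zip(self.loci[:-1], self.loci[1:]):
            if a.chromosome != b.chromosome:
                fractions.append(0.5)
            elif a.recomb_fraction_to_next is not None:
                fractions.append(a.recomb_fraction_to_next)
            else:
                fractions.append(0.5)
        return fractions

    def swapped_parents(self) -> "CrossConfig":
        return CrossConfig(loci=list(self.loci), parent1=dict(self.parent2),
                           parent2=dict(self.parent1), killers=list(self.killers))


# ----------------------------------------------------------------------
# Config serialization (YAML)
# ----------------------------------------------------------------------

def cross_config_from_dict(d: Mapping) -> CrossConfig:
    """Build a CrossConfig from a plain mapping (the YAML config format).

    Killers may give explicit ``kappa``/``pi`` or name a truncation
    ``preset`` (Ta/Tb/Tc/Td/Te)."""
    loci = [Locus(id=l["id"], chromosome=l.get("chromosome", "chr1"),
                  position=int(l["position"]),
                  recomb_fraction_to_next=l.get("recomb_fraction_to_next"))
            for l in d["loci"]]
    parents = d["parents"]
    killers = []
    for k in d.get("killers", []):
        if "preset" in k:
            killers.append(KillerAllele.from_preset(
                k["id"], k["locus"], k["preset"],
                resistance_set=k.get("resistance_set")))
        else:
            killers.append(KillerAllele(
                id=k["id"], locus=k["locus"], kappa=float(k["kappa"]),
                pi=float(k["pi"]),
                resistance_set=(frozenset(k["resistance_set"])
                                if k.get("resistance_set") else None)))
    return CrossConfig(loci=loci, parent1=dict(parents["parent1"]),
                       parent2=dict(parents["parent2"]), killers=killers)


def load_cross_config(path) -> CrossConfig:
    import yaml
    with open(path) as fh:
        return cross_config_from_dict(yaml.safe_load(fh))


def save_cross_config(config: CrossConfig, path) -> None:
    import yaml
    d = {
        "loci": [{"id": l.id, "chromosome": l.chromosome, "position": l.position,
                  **({"recomb_fraction_to_next": l.recomb_fraction_to_next}
                     if l.recomb_fraction_to_next is not None else {})}
                 for l in config.loci],
        "parents": {"parent1": dict(config.parent1),
                    "parent2": dict(config.parent2)},
        "killers": [{"id": k.id, "locus": k.locus, "kappa": k.kappa,
                     "pi": k.pi, "resistance_set": sorted(k.resistance_set)}
                    for k in config.killers],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


# ----------------------------------------------------------------------
# Spore survival
# ----------------------------------------------------------------------

def spore_survival_probability(
    spore_genotype: Mapping[str, str],
    killers: Iterable[KillerAllele],
) -> float:
    """Survival probability of one spore exposed to every killer poison
    present in the parental diploid.

    survival = prod_k [1 - kappa_k * (1 - prot(spore, k))] where
    prot(spore, k) is the best antidote efficiency among alleles carried by
    the spore whose resistance set covers killer k (0 if none).
    """
    killers = list(killers)
    registry = {k.id: k for k in killers}
    carried = set(spore_genotype.values())
    # protective alleles may also be killer-derived alleles not poisoning
    # this cross; callers can pass them in `killers` to register their pi.
    survival = 1.0
    for k in killers:
        if k.kappa == 0.0:
            continue
        if k.locus not in spore_genotype:
            raise KeyError(
                f"spore genotype missing killer locus {k.locus!r} (killer {k.id})")
        prot = 0.0
        for allele in carried:
            a = registry.get(allele)
            if a is not None and k.id in a.resistance_set:
                prot = max(prot, a.pi)
        survival *= 1.0 - k.kappa * (1.0 - prot)
    # even kappa=0 killers require their locus typed, per contract
    for k in killers:
        if k.locus not in spore_genotype:
            raise KeyError(
                f"spore genotype missing killer locus {k.locus!r} (killer {k.id})")
    return survival


# ----------------------------------------------------------------------
# Tetrad enumeration
# ----------------------------------------------------------------------

def enumerate_tetrad_patterns(config: CrossConfig):
    """Yield (probability, spore_genotypes) over tetrad segregation
    patterns.

    The four spores form two origin-heterogeneous pairs — (spore0, spore2)
    and (spore1, spore3) — each containing one parent1- and one
    parent2-derived strand at every locus, which enforces 2:2 segregation.
    Per interval each pair independently swaps origins with probability r.
    """
    loci = config.loci
    if not loci:
        yield 1.0, [dict(), dict(), dict(), dict()]
        return
    fractions = config.interval_fractions()
    n_int = len(fractions)
    # state: origins (o0, o1) of spores 0 and 1 (0 = parent1, 1 = parent2);
    # spore2 = 1-o0, spore3 = 1-o1.
    for flips in itertools.product((0, 1), repeat=2 * n_int):
        prob = 1.0
        for i, r in enumerate(fractions):
            f1, f2 = flips[2 * i], flips[2 * i + 1]
            prob *= (r if f1 else 1.0 - r) * (r if f2 else 1.0 - r)
        if prob == 0.0:
            continue
        o0, o1 = 0, 0
        genotypes = [dict() for _ in range(4)]
        for j, locus in enumerate(loci):
            if j > 0:
                o0 ^= flips[2 * (j - 1)]
                o1 ^= flips[2 * (j - 1) + 1]
            p1a = config.parent1[locus.id]
            p2a = config.parent2[locus.id]
            genotypes[0][locus.id] = p2a if o0 else p1a
            genotypes[1][locus.id] = p2a if o1 else p1a
            genotypes[2][locus.id] = p1a if o0 else p2a
            genotypes[3][locus.id] = p1a if o1 else p2a
        yield prob, genotypes


def _pattern_survivals(config: CrossConfig):
    killers = config.present_killers()
    for prob, genotypes in enumerate_tetrad_patterns(config):
        s = [spore_survival_probability(g, killers) for g in genotypes]
        yield prob, genotypes, s


def tetrad_outcome_distribution(config: CrossConfig) -> np.ndarray:
    """Exact probability distribution of the number of viable spores per
    tetrad (array of length 5, indices 0..4; sums to 1)."""
    dist = np.zeros(5)
    for prob, _genotypes, s in _pattern_survivals(config):
        # Poisson-binomial over the four spores
        pb = np.zeros(5)
        pb[0] = 1.0
        for si in s:
            pb[1:] = pb[1:] * (1.0 - si) + pb[:-1] * si
            pb[0] *= 1.0 - si
        dist += prob * pb
    return dist


def expected_viability(config: CrossConfig) -> float:
    """Expected fraction of viable spores, in [0, 1]."""
    dist = tetrad_outcome_distribution(config)
    return float(np.dot(dist, np.arange(5)) / 4.0)


def expected_viable_allele_frequency(
    config: CrossConfig, locus: str, allele: str
) -> float:
    """Expected frequency of ``allele`` at ``locus`` in a large pool of
    surviving spores (ratio of expectations)."""
    if locus not in {l.id for l in config.loci}:
        raise KeyError(f"locus {locus!r} not in cross configuration")
    num = 0.0
    den = 0.0
    for prob, genotypes, s in _pattern_survivals(config):
        for g, si in zip(genotypes, s):
            den += prob * si
            if g[locus] == allele:
                num += prob * si
    if den <= 0.0:
        raise ValueError("no viable spores under this configuration")
    return num / den


# ----------------------------------------------------------------------
# Maximum-likelihood fitting of killer parameters
# ----------------------------------------------------------------------

@dataclass
class FitResult:
    estimates: Dict[str, Tuple[float, float]]   # killer id -> (kappa, pi)
    log_likelihood: float
    converged: bool
    non_identifiable: List[str]                  # e.g. "kappa:cw9"
    at_boundary: List[str]

    def __repr__(self):  # compact, for logs
        est = ", ".join(f"{k}: kappa={v[0]:.3f} pi={v[1]:.3f}"
                        for k, v in self.estimates.items())
        return (f"FitResult({est}; logL={self.log_likelihood:.3f}, "
                f"converged={self.converged})")


def _collapse_spores(records, killer_loci: Set[str]):
    """Collapse spores to (genotype-at-killer-loci, viable) -> count."""
    counts: Dict[Tuple[Tuple[str, str], ...], List[int]] = {}
    for rec in records:
        for spore in rec.spores:
            try:
                key = tuple(sorted((l, spore.genotypes[l]) for l in killer_loci))
            except KeyError as exc:
                raise KeyError(
                    f"spore in tetrad {rec.tetrad_id} lacks genotype at "
                    f"killer locus {exc.args[0]!r}") from exc
            counts.setdefault(key, [0, 0])
            counts[key][1 if spore.viable else 0] += 1
    return counts


def fit_killer_parameters(
    records: Sequence,
    model_structure: Sequence[KillerAllele],
    grid_step: float = 0.05,
) -> FitResult:
    """Fit (kappa, pi) for each killer in ``model_structure`` by maximum
    likelihood over spore viability outcomes.

    The likelihood treats each spore independently with survival probability
    from :func:`spore_survival_probability`.  Optimization is a deterministic
    coarse grid (``grid_step``) over all free parameters followed by bounded
    local refinement; estimates are clipped to [0, 1].  Parameters that the
    data cannot constrain (no carrier spores observed -> pi; no non-carrier
    spores -> kappa) are flagged, not silently returned.
    """
    killers = list(model_structure)
    killer_loci = {k.locus for k in killers}
    counts = _collapse_spores(records, killer_loci)
    genotype_keys = list(counts.keys())
    dead = np.array([counts[g][0] for g in genotype_keys], dtype=float)
    alive = np.array([counts[g][1] for g in genotype_keys], dtype=float)

    # identifiability flags from observed genotype composition
    non_identifiable = []
    for k in killers:
        carriers = sum(counts[g][0] + counts[g][1] for g in genotype_keys
                       if dict(g)[k.locus] == k.id)
        total = int(dead.sum() + alive.sum())
        if carriers == total:
            non_identifiable.append(f"kappa:{k.id}")
        if carriers == 0:
            non_identifiable.append(f"pi:{k.id}")

    def survival_vector(theta: np.ndarray) -> np.ndarray:
        ks = [
            KillerAllele(id=k.id, locus=k.locus,
                         kappa=float(np.clip(theta[2 * i], 0, 1)),
                         pi=float(np.clip(theta[2 * i + 1], 0, 1)),
                         resistance_set=k.resistance_set)
            for i, k in enumerate(killers)
        ]
        return np.array([
            spore_survival_probability(dict(g), ks) for g in genotype_keys
        ])

    def negloglik(theta: np.ndarray) -> float:
        s = np.clip(survival_vector(theta), 1e-12, 1.0 - 1e-12)
        return -float(np.dot(alive, np.log(s)) + np.dot(dead, np.log(1.0 - s)))

    grid = np.arange(0.0, 1.0 + 1e-9, grid_step)
    best_theta, best_val = None, np.inf
    for combo in itertools.product(grid, repeat=2 * len(killers)):
        theta = np.asarray(combo)
        val = negloglik(theta)
        if val < best_val - 1e-12:
            best_val, best_theta = val, theta
    res = optimize.minimize(
        negloglik, best_theta, method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * (2 * len(killers)))
    theta = np.clip(res.x if res.fun <= best_val else best_theta, 0.0, 1.0)
    logl = -min(res.fun, best_val)

    estimates = {
        k.id: (float(theta[2 * i]), float(theta[2 * i + 1]))
        for i, k in enumerate(killers)
    }
    at_boundary = []
    for k in killers:
        kap, pi = estimates[k.id]
        if kap < 1e-6 or kap > 1 - 1e-6:
            at_boundary.append(f"kappa:{k.id}")
        if pi < 1e-6 or pi > 1 - 1e-6:
            at_boundary.append(f"pi:{k.id}")
    return FitResult(estimates=estimates, log_likelihood=logl,
                     converged=bool(res.success) or best_theta is not None,
                     non_identifiable=non_identifiable, at_boundary=at_boundary)
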
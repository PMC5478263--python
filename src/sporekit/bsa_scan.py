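"""Bulk segregant analysis of pooled viable-progeny sequencing.

Many viable progeny of a cross are pooled and sequenced; at each SNP that
distinguishes the two parents, the reference-allele frequency among the
pool's reads is computed.  Away from any selection, the frequency hovers
around 0.5; a heterozygous spore killer depletes the non-carrier parental
alleles in its vicinity, producing a broad transmission-distortion trough
(or peak) around the killer locus.  The stages here are: depth-filtered
allele frequencies, a centered rolling-median trend, threshold-based
distortion-region detection, and donor-segment inference for backcross
strains (segregating SNPs reveal which genome blocks the backcross parent
carries).

The count table is expected to be produced upstream of this package (read
alignment, base/mapping-quality filtering and per-base counting happen
there); this module consumes the TSV with columns
chrom, pos, ref, alt, ref_count, alt_count.
Coordinates are 1-based inclusive internally; BED export is 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_table",
    "write_track",
    "compute_allele_frequencies",
    "rolling_median_trend",
    "DistortionRegion",
    "detect_distortion_regions",
    "DonorSegment",
    "infer_donor_segments",
    "regions_to_bed",
    "plot_frequency_track",
]

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


def read_count_table(path) -> pd.DataFrame:
    """Read a per-SNP allele-count TSV (header required) and validate it."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise ValueError("negative read counts")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise ValueError(
            f"duplicate (chrom, pos) at line {int(dup.idxmax()) + 2}")
    for chrom, grp in df.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(f"positions not sorted on {chrom}")
    return df


def compute_allele_frequencies(counts: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Reference-allele frequency per SNP, keeping only SNPs whose total
    informative depth (ref_count + alt_count) reaches ``min_depth``.

    ref_freq = ref_count / (ref_count + alt_count).
    """
    total = counts["ref_count"] + counts["alt_count"]
    kept = counts.loc[total >= min_depth].copy()
    kept_total = kept["ref_count"] + kept["alt_count"]
    kept["ref_freq"] = kept["ref_count"] / kept_total
    return kept[["chrom", "pos", "ref_freq"]].reset_index(drop=True)


def rolling_median_trend(track: pd.DataFrame, window: int = 45) -> pd.DataFrame:
    """Centered rolling median of ref_freq over ``window`` consecutive
    SNPs, computed per chromosome.  The trend is undefined (NaN) where a
    full window does not fit — the first and last (window-1)/2 SNPs of each
    chromosome — and for chromosomes with fewer SNPs than the window."""
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    out = track.copy()
    trends = []
    for chrom, grp in out.groupby("chrom", sort=False):
        if len(grp) < window:
            logger.warning("chromosome %s has %d SNPs < window %d; no trend",
                           chrom, len(grp), window)
            trends.append(pd.Series(np.nan, index=grp.index))
        else:
            trends.append(grp["ref_freq"].rolling(window, center=True).median())
    out["trend"] = pd.concat(trends)
    return out


def _runs(mask: np.ndarray):
    """Yield (start, end) index pairs (inclusive) of maximal True runs."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e])


@dataclass
class DistortionRegion:
    chrom: str
    start: int
    end: int
    direction: str        # which parental allele set is under-represented
    extremum: int         # position of maximal |trend - 0.5|
    extremum_deviation: float
    n_snps: int


def detect_distortion_regions(
    track: pd.DataFrame,
    delta: float = 0.15,
    min_run: int = 45,
) -> List[DistortionRegion]:
    """Maximal runs of >= ``min_run`` consecutive SNPs whose trend deviates
    from 0.5 by at least ``delta`` in a consistent direction.

    direction "reference_underrepresented" marks trend < 0.5 (the reference
    parent's alleles depleted among viable progeny), and conversely."""
    if "trend" not in track.columns:
        raise ValueError("track has no trend column; run rolling_median_trend")
    regions: List[DistortionRegion] = []
    for chrom, grp in track.groupby("chrom", sort=False):
        dev = grp["trend"].to_numpy() - 0.5
        pos = grp["pos"].to_numpy()
        for direction, mask in (
            ("reference_underrepresented", dev <= -delta),
            ("variant_underrepresented", dev >= delta),
        ):
            mask = mask & ~np.isnan(dev)
            for s, e in _runs(mask):
                if e - s + 1 < min_run:
                    continue
                seg = np.abs(dev[s:e + 1])
                imax = int(np.argmax(seg))
                regions.append(DistortionRegion(
                    chrom=chrom, start=int(pos[s]), end=int(pos[e]),
                    direction=direction, extremum=int(pos[s + imax]),
                    extremum_deviation=float(seg[imax]), n_snps=e - s + 1))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


@dataclass
class DonorSegment:
    chrom: str
    start: int
    end: int
    n_snps: int


def infer_donor_segments(
    track: pd.DataFrame,
    max_ref_freq: float = 0.95,
    min_run: int = 20,
) -> List[DonorSegment]:
    """Segments of the backcross donor genome, detected as maximal runs of
    >= ``min_run`` SNPs still segregating in the pool (ref_freq <=
    ``max_ref_freq``); fixed-reference stretches are recipient genome.
    Segment bounds are the first/last SNP positions of the run."""
    segments: List[DonorSegment] = []
    for chrom, grp in track.groupby("chrom", sort=False):
        freq = grp["ref_freq"].to_numpy()
        pos = grp["pos"].to_numpy()
        for s, e in _runs(freq <= max_ref_freq):
            if e - s + 1 < min_run:
                continue
            segments.append(DonorSegment(chrom=chrom, start=int(pos[s]),
                                         end=int(pos[e]), n_snps=e - s + 1))
    segments.sort(key=lambda r: (r.chrom, r.start))
    return segments


def regions_to_bed(regions: Sequence, path) -> None:
    """Write regions/segments as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            name = getattr(r, "direction", "donor_segment")
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def write_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_frequency_track(
    track: pd.DataFrame,
    path,
    regions: Optional[Sequence[DistortionRegion]] = None,
) -> None:
    """Per-chromosome scatter of SNP reference-allele frequencies with the
    rolling-median trend line and optional shaded distortion regions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(track["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2.5 * len(chroms)),
                             squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        grp = track[track["chrom"] == chrom]
        ax.plot(grp["pos"] / 1e6, grp["ref_freq"], ".", ms=2, color="0.6",
                label="SNP ref freq")
        if "trend" in grp.columns:
            ax.plot(grp["pos"] / 1e6, grp["trend"], "-", color="crimson",
                    lw=1.5, label="rolling median")
        for r in regions or []:
            if r.chrom == chrom:
                ax.axvspan(r.start / 1e6, r.end / 1e6, color="gold", alpha=0.3)
        ax.axhline(0.5, color="k", lw=0.5, ls="--")
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("ref allele freq")
        ax.set_title(str(chrom))
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
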
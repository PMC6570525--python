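"""Anchor-aligned, transcript-averaged occupancy profiles.

Profiles average site occupancies over transcripts aligned at a common
anchor (TSS, pA site, stop codon, or generic gene start/end) in a fixed
offset window, on the sense or antisense strand.  Candidate transcripts are
length-filtered and required to have no neighboring gene on the relevant
flank, so the profile reflects the central gene only.  The averaged profile
is smoothed with a centered moving average (window truncated at the edges),
a percentile bootstrap over transcripts gives a confidence band, and the
result is min-max normalized per profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, Transcript
from .crosslink import FactorDataset

log = logging.getLogger(__name__)

DEFAULT_EXCLUDE_CLASSES = ("snRNA", "rRNA", "tRNA")


@dataclass
class MetageneProfile:
    align_point: str          # TSS | pA | stop_codon | gene_start | gene_end
    strand_mode: str          # sense | antisense
    offsets: np.ndarray       # -W..+W
    mean_occ: np.ndarray      # min-max normalized smoothed mean
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_transcripts: int
    smoothing_window: int
    raw_mean: np.ndarray | None = None  # smoothed mean before normalization

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.offsets, "mean": self.mean_occ,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n": self.n_transcripts,
        })


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with window truncation at the edges.

    Works on the last axis of a 1-D or 2-D array.  The effective window
    shrinks near the boundaries instead of padding, so no data outside the
    profile is invented.
    """
    if window <= 1:
        return np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    v = np.atleast_2d(np.asarray(values, dtype=float))
    half = window // 2
    n = v.shape[-1]
    cs = np.concatenate([np.zeros((v.shape[0], 1)), np.cumsum(v, axis=-1)],
                        axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    out = (cs[:, hi] - cs[:, lo]) / (hi - lo)
    return out[0] if np.ndim(values) == 1 else out


def eligible_transcripts(annotation_set: AnnotationSet, align_point: str,
                         strand_mode: str = "sense", window: int = 700,
                         min_length: int = 1500,
                         classes: tuple[str, ...] = ("mRNA",)
                         ) -> list[Transcript]:
    """Transcripts usable for a clean profile at the given anchor.

    Keeps transcripts of the requested classes with length >= min_length and
    no other same-class transcript within `window` nt on the flank outside
    the anchor (upstream of the TSS, or downstream of the pA site), on the
    same strand for sense profiles or on the opposite strand for antisense
    profiles.  Short ncRNA profiles pass min_length=0 to drop the length
    filter.
    """
    if align_point not in ("TSS", "pA", "stop_codon", "gene_start", "gene_end"):
        raise ValueError(f"unknown align point {align_point!r}")
    if strand_mode not in ("sense", "antisense"):
        raise ValueError(f"unknown strand mode {strand_mode!r}")
    candidates = [t for t in annotation_set.by_class(*classes)
                  if t.length >= min_length]
    # 3'-anchored profiles (pA, stop codon) check the downstream flank
    upstream_of_anchor = align_point in ("TSS", "gene_start")
    out = []
    for t in candidates:
        # genomic interval of the flank that must be free of neighbors
        if (t.strand == "+") == upstream_of_anchor:
            flank = (t.start - window, t.start)
        else:
            flank = (t.end, t.end + window)
        check_strand = t.strand if strand_mode == "sense" else \
            ("-" if t.strand == "+" else "+")
        neighbors = [o for o in annotation_set.overlapping(
            t.chrom, max(flank[0], 0), flank[1], check_strand)
            if o.id != t.id and o.class_label in classes]
        if not neighbors:
            out.append(t)
    return out


def exclude_sites_in_regions(dataset: FactorDataset,
                             annotation_set: AnnotationSet,
                             region_classes: tuple[str, ...] = DEFAULT_EXCLUDE_CLASSES,
                             intervals: list[tuple[str, int, int, str]] | None = None
                             ) -> FactorDataset:
    """Remove sites overlapping denoising regions (strand-aware).

    By default drops sites in snRNAs, rRNAs and tRNAs; explicit intervals
    (chrom, start, end, strand) may be added, e.g. annotated NUT/CUT regions
    when testing whether an upstream signal originates from them.
    """
    s = dataset.sites
    if not len(s):
        return dataset
    remove = np.zeros(len(s), dtype=bool)
    region_set = {t.id for t in annotation_set.by_class(*region_classes)}
    for i, (chrom, pos, strand) in enumerate(zip(s["chrom"], s["pos"],
                                                 s["strand"])):
        for t in annotation_set.transcripts_at(chrom, int(pos), strand):
            if t.id in region_set:
                remove[i] = True
                break
        if not remove[i] and intervals:
            for c, start, end, st in intervals:
                if c == chrom and st == strand and start <= pos < end:
                    remove[i] = True
                    break
    log.info("%s: region exclusion removed %d/%d sites",
             dataset.factor, int(remove.sum()), len(s))
    return dataset.with_sites(s[~remove])


def profile_matrix(dataset: FactorDataset, transcripts: list[Transcript],
                   chrom_lengths: dict[str, int], align_point: str,
                   strand_mode: str = "sense", window: int = 700
                   ) -> np.ndarray:
    """Per-transcript occupancy rows over offsets -window..+window.

    Offsets run 5'->3' in transcript orientation; offsets beyond chromosome
    ends contribute 0 (observed absence).  In antisense mode the occupancy
    track of the opposite strand is read at the same genomic positions.
    """
    tracks = dataset.occupancy_arrays(chrom_lengths)
    width = 2 * window + 1
    mat = np.zeros((len(transcripts), width))
    for i, t in enumerate(transcripts):
        anchor = t.anchor(align_point)
        strand = t.strand if strand_mode == "sense" else \
            ("-" if t.strand == "+" else "+")
        arr = tracks[(t.chrom, strand)]
        if t.strand == "+":
            lo, hi = anchor - window, anchor + window + 1
            src = arr[max(lo, 0):min(hi, len(arr))]
            mat[i, max(lo, 0) - lo:max(lo, 0) - lo + len(src)] = src
        else:
            lo, hi = anchor - window, anchor + window + 1
            src = arr[max(lo, 0):min(hi, len(arr))]
            row = np.zeros(width)
            row[max(lo, 0) - lo:max(lo, 0) - lo + len(src)] = src
            mat[i] = row[::-1]  # flip to transcript orientation
    return mat


def average_profile(dataset: FactorDataset, transcripts: list[Transcript],
                    chrom_lengths: dict[str, int], align_point: str,
                    strand_mode: str = "sense", window: int = 700,
                    smooth: int = 41, n_boot: int = 1500, ci: float = 0.95,
                    rng: np.random.Generator | None = None,
                    normalize: bool = True) -> MetageneProfile:
    """Transcript-averaged occupancy profile with bootstrap confidence band.

    The per-offset mean over transcripts is smoothed by a centered moving
    average; the same smoothing is applied inside each bootstrap replicate
    (resampling transcripts with replacement) so the band matches the curve.
    The profile and band are then min-max normalized together using the
    mean profile's extrema.  A constant profile cannot be normalized and is
    emitted as all zeros with a warning.
    """
    if not transcripts:
        raise ValueError("empty transcript list")
    rng = rng or np.random.default_rng()
    mat = profile_matrix(dataset, transcripts, chrom_lengths, align_point,
                         strand_mode, window)
    n = len(transcripts)
    mean = moving_average(mat.mean(axis=0), smooth)
    if n_boot > 0:
        # multinomial resampling weights: mean of resampled rows == w @ mat / n
        weights = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
        boot = moving_average((weights / n) @ mat, smooth)
        alpha = (1.0 - ci) / 2.0
        lo = np.quantile(boot, alpha, axis=0)
        hi = np.quantile(boot, 1.0 - alpha, axis=0)
        lo, hi = np.minimum(lo, mean), np.maximum(hi, mean)
    else:
        lo = hi = mean.copy()
    offsets = np.arange(-window, window + 1)
    raw_mean = mean.copy()
    if normalize:
        mmin, mmax = float(mean.min()), float(mean.max())
        if mmax - mmin <= 0:
            log.warning("constant profile: min-max normalization degenerate; "
                        "emitting all-zero profile")
            mean = np.zeros_like(mean)
            lo = np.zeros_like(lo)
            hi = np.zeros_like(hi)
        else:
            scale = mmax - mmin
            mean = (mean - mmin) / scale
            lo = (lo - mmin) / scale
            hi = (hi - mmin) / scale
    return MetageneProfile(align_point=align_point, strand_mode=strand_mode,
                           offsets=offsets, mean_occ=mean, ci_low=lo,
                           ci_high=hi, n_transcripts=n,
                           smoothing_window=smooth, raw_mean=raw_mean)


def stacked_profiles(profiles: dict[str, MetageneProfile]) -> pd.DataFrame:
    """Heatmap-ready matrix: factors as rows, offsets as columns."""
    return pd.DataFrame({name: p.mean_occ for name, p in profiles.items()},
                        index=next(iter(profiles.values())).offsets).T
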
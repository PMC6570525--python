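"""Positional k-mer enrichment around cross-linked T sites.

Windows of sequence are extracted around high-confidence cross-link sites,
oriented so the cross-linked base reads as T at offset 0.  k-mers are
counted at start offsets -5..+5 relative to the cross-link, and each
(k-mer, offset) cell is scored against an i.i.d. background with yeast base
frequencies (P_A = P_T = 0.31, P_C = P_G = 0.19):

    enrichment(kmer, i) = (n_{kmer,i} + 1) / (N * prod_j P_{kmer[j]})

The position coinciding with the cross-link carries background probability
1 ("T bias correction": every window has T there by construction), and a
cell whose k-mer covers offset 0 with a non-T base is infeasible and
masked.  The matrix is reported as log2 enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .annotations import GenomeSequence, reverse_complement
from .crosslink import FactorDataset

log = logging.getLogger(__name__)

YEAST_BACKGROUND = {"A": 0.31, "T": 0.31, "C": 0.19, "G": 0.19}


class MotifError(ValueError):
    pass


def select_top_sites(dataset: FactorDataset, max_sites: int = 5000
                     ) -> FactorDataset:
    """The `max_sites` most significant sites, deterministically ordered.

    Ranked by ascending p-value; ties broken by descending occupancy (0 if
    not computed), then by coordinate.
    """
    s = dataset.sites.copy()
    occ = s["occupancy"] if "occupancy" in s.columns else pd.Series(0.0,
                                                                    index=s.index)
    s["_occ"] = occ.fillna(0.0)
    s = s.sort_values(["p_value", "_occ", "chrom", "pos", "strand"],
                      ascending=[True, False, True, True, True],
                      kind="mergesort")
    s = s.head(max_sites).drop(columns="_occ")
    return dataset.with_sites(s)


def extract_windows(dataset: FactorDataset, genome: GenomeSequence,
                    k: int = 4, flank: int = 5) -> list[str]:
    """Oriented sequence windows covering k-mer starts -flank..+flank.

    For a plus-strand site at p the window is genome[p-flank : p+flank+k];
    minus-strand windows take the reverse complement of the mirrored span
    so the cross-linked T reads as T at the center index.  Windows running
    over a chromosome end are dropped, as are sites whose oriented center
    base is not T (a data inconsistency); both counts are logged.
    """
    left, right = flank, flank + k - 1  # span around the cross-linked T
    windows: list[str] = []
    n_bounds = n_non_t = 0
    for chrom, pos, strand in zip(dataset.sites["chrom"], dataset.sites["pos"],
                                  dataset.sites["strand"]):
        seq = genome.chroms[chrom]
        pos = int(pos)
        if strand == "+":
            lo, hi = pos - left, pos + right + 1
            if lo < 0 or hi > len(seq):
                n_bounds += 1
                continue
            win = seq[lo:hi]
        else:
            lo, hi = pos - right, pos + left + 1
            if lo < 0 or hi > len(seq):
                n_bounds += 1
                continue
            win = reverse_complement(seq[lo:hi])
        if win[left] != "T":
            n_non_t += 1
            continue
        windows.append(win)
    if n_bounds:
        log.info("%s: dropped %d windows at chromosome boundaries",
                 dataset.factor, n_bounds)
    if n_non_t:
        log.info("%s: dropped %d sites without T at the cross-link position",
                 dataset.factor, n_non_t)
    return windows


@dataclass
class KmerEnrichmentMatrix:
    counts: pd.DataFrame       # k-mers x offsets, raw counts
    enrichment: pd.DataFrame   # ratio scale, NaN where infeasible
    log2_enrichment: pd.DataFrame
    feasible: pd.DataFrame     # bool mask
    n_windows: int
    k: int
    background: dict[str, float]
    t_bias_corrected: bool

    def cell(self, kmer: str, offset: int) -> float:
        return float(self.log2_enrichment.loc[kmer, offset])


def kmer_enrichment(windows: list[str], k: int = 4,
                    background: dict[str, float] | None = None,
                    flank: int = 5, pseudocount: float = 1.0,
                    t_bias_correction: bool = True) -> KmerEnrichmentMatrix:
    """Positional k-mer counts and enrichment over the background model.

    Offsets index the k-mer start relative to the cross-linked T (offset 0);
    with flank=5 and k=4 the windows span sequence positions -5..+8.  With
    `t_bias_correction` the background factor for the position covering the
    cross-link is 1 (the base is T by construction); without it, P_T is
    used, which overstates depletion of T-containing cells at the center.
    """
    if not windows:
        raise MotifError("empty window set")
    background = dict(background or YEAST_BACKGROUND)
    width = 2 * flank + k
    if any(len(w) != width for w in windows):
        raise MotifError(f"all windows must have length {width}")
    N = len(windows)
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    offsets = list(range(-flank, flank + 1))
    counts = pd.DataFrame(0, index=kmers, columns=offsets, dtype=int)
    arr = counts.to_numpy()
    kmer_idx = {km: i for i, km in enumerate(kmers)}
    for w in windows:
        for j, off in enumerate(offsets):
            sub = w[j:j + k]
            idx = kmer_idx.get(sub)
            if idx is not None:  # skip k-mers containing N
                arr[idx, j] += 1
    counts = pd.DataFrame(arr, index=kmers, columns=offsets)

    feasible = pd.DataFrame(True, index=kmers, columns=offsets)
    enr = pd.DataFrame(np.nan, index=kmers, columns=offsets)
    for j, off in enumerate(offsets):
        covers_center = -off if 0 <= -off < k else None  # k-mer index of offset 0
        for km in kmers:
            if covers_center is not None and km[covers_center] != "T":
                feasible.loc[km, off] = False
                continue
            p = 1.0
            for jj, base in enumerate(km):
                if t_bias_correction and covers_center == jj:
                    continue  # cross-link position contributes no factor
                p *= background[base]
            enr.loc[km, off] = (counts.loc[km, off] + pseudocount) / (N * p)
    log2_enr = np.log2(enr)
    return KmerEnrichmentMatrix(counts=counts, enrichment=enr,
                                log2_enrichment=log2_enr, feasible=feasible,
                                n_windows=N, k=k, background=background,
                                t_bias_corrected=t_bias_correction)


def write_enrichment_tsv(result: KmerEnrichmentMatrix, path) -> None:
    """log2 enrichment TSV: k-mers (lexicographic) x offsets, NA = masked."""
    result.log2_enrichment.to_csv(path, sep="\t", na_rep="NA",
                                  index_label="kmer")
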
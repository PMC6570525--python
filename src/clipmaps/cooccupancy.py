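"""Co-occupancy, co-localization and 2-D embedding of factor similarity.

Co-occupancy asks whether two factors bind the same transcripts: it is the
Pearson correlation, over all annotated transcripts, of the factors' total
occupancies.  Co-localization asks whether one factor's occupancy piles up
within +-40 nt of another factor's cross-link sites (the centered T itself
excluded); the windowed sums are normalized by row and column totals and
the final score is the Pearson correlation between rows of the normalized
matrix.  A t-SNE embedding of 1 - correlation distances visualizes the
factor similarity structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .annotations import AnnotationSet
from .crosslink import FactorDataset, transcript_total_occupancies

log = logging.getLogger(__name__)


def transcript_occupancy_table(datasets: list[FactorDataset],
                               annotation_set: AnnotationSet) -> pd.DataFrame:
    """Transcripts x factors matrix of total occupancy.

    Sites are assigned to transcripts strand-aware; a site overlapping
    several same-strand transcripts counts toward each of them.  Sites in no
    transcript are ignored.
    """
    cols = {d.factor: transcript_total_occupancies(d, annotation_set)
            for d in datasets}
    return pd.DataFrame(cols)


def cooccupancy_matrix(occupancy_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-transcript occupancies between factors.

    Symmetric with unit diagonal; a factor with a constant occupancy vector
    has undefined correlations, reported as NaN.
    """
    if len(occupancy_table) < 3:
        raise ValueError("need at least 3 transcripts")
    r = occupancy_table.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    constant = occupancy_table.std(axis=0) == 0
    for f in occupancy_table.columns[constant]:
        log.warning("factor %s has constant occupancy; correlations undefined", f)
        r.loc[f, :] = np.nan
        r.loc[:, f] = np.nan
    return r


@dataclass
class ColocalizationMatrix:
    z: pd.DataFrame   # raw windowed occupancy sums, z[f, f']
    C: pd.DataFrame   # normalized scores
    R: pd.DataFrame   # Pearson correlations between rows of C
    window: int
    n_sites: pd.Series


def colocalization(datasets: list[FactorDataset],
                   chrom_lengths: dict[str, int], window: int = 40,
                   denominator: str = "colrow") -> ColocalizationMatrix:
    """Windowed occupancy of each factor around each factor's sites.

    z[f, f'] sums factor f's occupancy at offsets -window..-1 and
    +1..+window around every cross-link site of factor f', same strand,
    with 0 where f has no verified site.  C divides z by the product of its
    column and row totals (`denominator="colrow"`; the transposed reading
    "rowcol" is available -- the final R is invariant to the choice up to
    the intermediate C).  R correlates the rows of C.
    """
    factors = [d.factor for d in datasets]
    tracks = {d.factor: d.occupancy_arrays(chrom_lengths) for d in datasets}
    # cumulative sums per factor for O(1) window sums
    csums = {
        f: {key: np.concatenate([[0.0], np.cumsum(arr)])
            for key, arr in tr.items()}
        for f, tr in tracks.items()
    }
    z = pd.DataFrame(0.0, index=factors, columns=factors)
    n_sites = pd.Series({d.factor: len(d.sites) for d in datasets})
    for dprime in datasets:
        s = dprime.sites
        if not len(s):
            continue
        for (chrom, strand), grp in s.groupby(["chrom", "strand"], sort=False):
            pos = grp["pos"].to_numpy()
            n = chrom_lengths[chrom]
            lo = np.clip(pos - window, 0, n)
            hi = np.clip(pos + window + 1, 0, n)
            for f in factors:
                cs = csums[f][(chrom, strand)]
                track = tracks[f][(chrom, strand)]
                win = cs[hi] - cs[lo] - track[np.clip(pos, 0, n - 1)]
                z.loc[f, dprime.factor] += float(win.sum())
    row_tot = z.sum(axis=1)  # sum over f' for each f
    col_tot = z.sum(axis=0)  # sum over f for each f'
    if denominator == "colrow":
        denom = np.outer(row_tot.to_numpy(), col_tot.to_numpy())
    elif denominator == "rowcol":
        denom = np.outer(col_tot.to_numpy(), row_tot.to_numpy())
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        C = pd.DataFrame(np.where(denom > 0, z.to_numpy() / denom, np.nan),
                         index=factors, columns=factors)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = pd.DataFrame(np.corrcoef(np.nan_to_num(C.to_numpy())),
                         index=factors, columns=factors)
    zero_rows = row_tot == 0
    for f in z.index[zero_rows]:
        log.warning("factor %s has zero co-localization totals", f)
        R.loc[f, :] = np.nan
        R.loc[:, f] = np.nan
    np.fill_diagonal(R.values, 1.0)
    return ColocalizationMatrix(z=z, C=C, R=R, window=window, n_sites=n_sites)


def embed_factors(similarity_matrix: pd.DataFrame, seed: int = 0,
                  perplexity: float = 30.0) -> pd.DataFrame:
    """2-D t-SNE embedding of a factor similarity (correlation) matrix.

    Distances are 1 - correlation (clipped at 0).  Perplexity is capped
    below the number of factors as t-SNE requires.  Fixed seed gives
    reproducible coordinates.
    """
    m = similarity_matrix.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("similarity matrix must be symmetric")
    dist = np.clip(1.0 - np.nan_to_num(m), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    n = dist.shape[0]
    perp = min(perplexity, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                random_state=seed, perplexity=perp)
    coords = tsne.fit_transform(dist)
    return pd.DataFrame(coords, index=similarity_matrix.index,
                        columns=["x", "y"])
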
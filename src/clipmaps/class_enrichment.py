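"""Transcript-class read counts and the double-centered log2 enrichment matrix.

Each factor's high-confidence reads are attributed to a single transcript
class per site by priority resolution; the factors x classes count matrix is
log2-transformed and double-centered (row mean and column mean subtracted,
grand mean added back) so that enrichment values sum to zero in both rows
and columns.  The centered score highlights which classes a factor binds
more than other factors do, corrected for class size and library depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import DETAILED_LABELS, AnnotationSet
from .crosslink import FactorDataset

log = logging.getLogger(__name__)

#: column order of the enrichment matrix (mRNA segments first)
CLASS_COLUMNS = ["utr5", "intron", "cds", "utr3", "rRNA", "tRNA", "snoRNA",
                 "snRNA", "SUT", "CUT", "NUT"]

UNANNOTATED = "unannotated"


def count_reads_by_class(dataset: FactorDataset,
                         annotation_set: AnnotationSet) -> pd.Series:
    """Read counts per transcript class (plus an 'unannotated' bucket).

    Each site contributes its full read coverage to the single class label
    at its position, resolved by the priority list.  The mRNA total of the
    headline distribution is the sum of utr5+cds+intron+utr3; these segment
    classes are reported separately here.
    """
    s = dataset.sites
    counts = pd.Series(0.0, index=list(CLASS_COLUMNS) + [UNANNOTATED])
    if not len(s):
        return counts
    codes = annotation_set.assign_site_classes(
        s["chrom"].to_numpy(), s["pos"].to_numpy(), s["strand"].to_numpy())
    cov = s["coverage"].to_numpy(dtype=float)
    for code in np.unique(codes):
        label = UNANNOTATED if code < 0 else DETAILED_LABELS[code]
        counts[label] += cov[codes == code].sum()
    return counts


def count_matrix(datasets: list[FactorDataset],
                 annotation_set: AnnotationSet,
                 drop_empty_classes: bool = True) -> pd.DataFrame:
    """Factors x classes raw read-count matrix (unannotated column dropped)."""
    rows = {d.factor: count_reads_by_class(d, annotation_set) for d in datasets}
    mat = pd.DataFrame(rows).T[CLASS_COLUMNS]
    if drop_empty_classes:
        empty = mat.columns[(mat.sum(axis=0) == 0)]
        if len(empty):
            log.info("dropping classes with no reads in any factor: %s",
                     list(empty))
            mat = mat.drop(columns=empty)
    return mat


@dataclass
class EnrichmentMatrix:
    raw_counts: pd.DataFrame    # X
    log_counts: pd.DataFrame    # X' = log2(X)
    centered: pd.DataFrame      # X~ (row and column sums vanish)
    class_cv: pd.Series         # per-class coefficient of variation

    @property
    def factors(self) -> list[str]:
        return list(self.raw_counts.index)

    @property
    def classes(self) -> list[str]:
        return list(self.raw_counts.columns)


def double_center(matrix: np.ndarray) -> np.ndarray:
    """Subtract row and column means, add back the grand mean.

    The unique linear correction after which every row sum and column sum
    is zero; additively separable structure r_f + s_c is annihilated.
    """
    m = np.asarray(matrix, dtype=float)
    return (m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True)
            + m.mean())


def enrichment_matrix(raw_counts: pd.DataFrame,
                      pseudocount: float = 1.0) -> EnrichmentMatrix:
    """log2 + double-centered enrichment scores from a raw count matrix.

    Zero cells are replaced by `pseudocount` before the log so the matrix
    stays finite (logged when applied).  A row or column that is entirely
    zero has no information and is rejected.
    """
    X = raw_counts.astype(float)
    zero_rows = X.index[(X.sum(axis=1) == 0)]
    zero_cols = X.columns[(X.sum(axis=0) == 0)]
    if len(zero_rows) or len(zero_cols):
        raise ValueError(
            f"all-zero rows/columns in count matrix: factors "
            f"{list(zero_rows)}, classes {list(zero_cols)}")
    n_zero = int((X.to_numpy() == 0).sum())
    if n_zero:
        log.info("replacing %d zero count cells with pseudocount %g",
                 n_zero, pseudocount)
        X = X.mask(X == 0, pseudocount)
    logX = np.log2(X)
    centered = pd.DataFrame(double_center(logX.to_numpy()),
                            index=X.index, columns=X.columns)
    cv = class_dispersion(raw_counts)
    return EnrichmentMatrix(raw_counts=raw_counts, log_counts=logX,
                            centered=centered, class_cv=cv)


def class_dispersion(raw_counts: pd.DataFrame) -> pd.Series:
    """Coefficient of variation of per-factor class fractions, per class.

    Rows are normalized to fractions; for each class the CV is the
    population standard deviation over factors divided by the mean.  A class
    with zero mean fraction is reported as NaN (missing); with a single
    factor the CV is 0 by convention.
    """
    fractions = raw_counts.div(raw_counts.sum(axis=1), axis=0)
    if len(fractions) == 1:
        log.warning("class dispersion with a single factor is 0 by convention")
        return pd.Series(0.0, index=raw_counts.columns, name="cv")
    mean = fractions.mean(axis=0)
    sd = fractions.std(axis=0, ddof=0)
    cv = sd / mean
    cv[mean == 0] = np.nan
    cv.name = "cv"
    return cv
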
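"""Linking occupancy to translation and decay: codon scores, feature curves,
the half-life surplus-binding model and likelihood-ratio feature tests.

The surplus-binding model decomposes a factor's total occupancy on an mRNA
into baseline binding to all transcripts (intercept b) and additional
binding while the transcript is being degraded, proportional to its
half-life (slope a): occupancy = a * t_half + b.  A factor recruited only
during degradation has a high a/b ratio; a factor bound to intact mRNAs has
a near 0.

Feature significance uses a multivariate linear model of per-nucleotide
occupancy on transcript length, codon optimality, expression and half-life;
each feature's contribution is scored by the likelihood-ratio test against
the model with that feature removed (1 degree of freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(c for c in ("".join(p) for p in product("ACGT", repeat=3))
                     if c not in STOP_CODONS)

FEATURES = ("length", "optimality", "expression", "halflife")


class TranslationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# codon optimality and composition


def transcript_optimality(cds_sequence: str,
                          codon_score_table: dict[str, float]) -> float:
    """Unweighted mean codon-optimality score over the reading frame."""
    if len(cds_sequence) % 3 != 0:
        raise TranslationError(
            f"CDS length {len(cds_sequence)} not divisible by 3")
    total = 0.0
    n = len(cds_sequence) // 3
    if n == 0:
        raise TranslationError("empty CDS")
    for i in range(0, len(cds_sequence), 3):
        codon = cds_sequence[i:i + 3]
        try:
            total += codon_score_table[codon]
        except KeyError:
            raise TranslationError(
                f"codon {codon!r} at position {i} not in score table") from None
    return total / n


def codon_fractions(cds_sequence: str,
                    codons: tuple[str, ...] = SENSE_CODONS) -> pd.Series:
    """Fraction of each codon among the reading frame's sense codons."""
    if len(cds_sequence) % 3 != 0:
        raise TranslationError(
            f"CDS length {len(cds_sequence)} not divisible by 3")
    counts = pd.Series(0.0, index=list(codons))
    n = 0
    for i in range(0, len(cds_sequence), 3):
        codon = cds_sequence[i:i + 3]
        if codon in counts.index:
            counts[codon] += 1
            n += 1
    if n == 0:
        raise TranslationError("CDS contains no sense codons")
    return counts / n


def codon_fraction_matrix(cds_by_transcript: dict[str, str],
                          codons: tuple[str, ...] = SENSE_CODONS
                          ) -> pd.DataFrame:
    """Transcripts x codons fraction matrix from CDS sequences."""
    rows = {tid: codon_fractions(seq, codons)
            for tid, seq in cds_by_transcript.items()}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# codon enrichment


@dataclass
class CodonEnrichmentResult:
    scores: pd.DataFrame  # columns: score, ci_low, ci_high per codon
    n_transcripts: int
    ci: float


def codon_enrichment(occupancies: pd.Series, fractions: pd.DataFrame,
                     n_boot: int = 1000, ci: float = 0.90,
                     rng: np.random.Generator | None = None
                     ) -> CodonEnrichmentResult:
    """Occupancy-weighted mean codon fraction over the unweighted mean.

    For each codon c, score = sum_t w_t F_{c,t} / mean_t F_{c,t}, with
    weights w_t = occ(t) / sum occ.  Uniform occupancy gives every codon a
    score of exactly 1.  Confidence intervals come from bootstrapping
    transcripts with replacement (the full set size each draw).
    """
    common = fractions.index.intersection(occupancies.index)
    occ = occupancies.loc[common].to_numpy(dtype=float)
    F = fractions.loc[common].to_numpy(dtype=float)
    T = len(common)
    if T == 0 or occ.sum() <= 0:
        raise TranslationError("no transcripts with positive total occupancy")
    rng = rng or np.random.default_rng()

    def score(o: np.ndarray, f: np.ndarray) -> np.ndarray:
        w = o / o.sum()
        return (w @ f) / f.mean(axis=0)

    point = score(occ, F)
    if n_boot > 0:
        boots = np.empty((n_boot, F.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, T, size=T)
            boots[b] = score(occ[idx], F[idx])
        alpha = (1.0 - ci) / 2.0
        lo = np.quantile(boots, alpha, axis=0)
        hi = np.quantile(boots, 1.0 - alpha, axis=0)
    else:
        lo = hi = point
    out = pd.DataFrame({"score": point, "ci_low": lo, "ci_high": hi},
                       index=fractions.columns)
    return CodonEnrichmentResult(scores=out, n_transcripts=T, ci=ci)


# ---------------------------------------------------------------------------
# occupancy vs feature curves


def quantile_trim(values: pd.Series, lo: float = 0.05, hi: float = 0.95
                  ) -> pd.Series:
    qlo, qhi = values.quantile([lo, hi])
    return values[(values >= qlo) & (values <= qhi)]


def occupancy_vs_feature_curve(features: pd.DataFrame, feature_name: str,
                               occupancy_col: str = "occupancy",
                               trim_quantiles: tuple[float, float] = (0.05, 0.95),
                               window_frac: float = 0.10, n_boot: int = 1000,
                               ci: float = 0.95,
                               rng: np.random.Generator | None = None
                               ) -> pd.DataFrame:
    """Sliding-window mean of occupancy along a ranked transcript feature.

    Transcripts are trimmed to the feature's [5%, 95%] quantile range and
    sorted by the feature; the curve is the centered moving-window mean of
    occupancy (window = `window_frac` of the retained transcripts), with a
    percentile bootstrap band over transcripts.
    """
    from .metagene import moving_average

    trimmed_idx = quantile_trim(features[feature_name], *trim_quantiles).index
    sub = features.loc[trimmed_idx, [feature_name, occupancy_col]].dropna()
    n = len(sub)
    if n < 20:
        raise TranslationError(
            f"only {n} transcripts after trimming (need >= 20)")
    sub = sub.sort_values(feature_name)
    window = max(1, int(round(window_frac * n)))
    if window % 2 == 0:
        window += 1
    x = sub[feature_name].to_numpy(dtype=float)
    y = sub[occupancy_col].to_numpy(dtype=float)
    curve = moving_average(y, window)
    if n_boot > 0:
        rng = rng or np.random.default_rng()
        boots = np.empty((n_boot, n))
        for b in range(n_boot):
            idx = np.sort(rng.integers(0, n, size=n))
            boots[b] = moving_average(y[idx], window)
        alpha = (1.0 - ci) / 2.0
        lo = np.quantile(boots, alpha, axis=0)
        hi = np.quantile(boots, 1.0 - alpha, axis=0)
    else:
        lo = hi = curve
    return pd.DataFrame({feature_name: moving_average(x, window),
                         "occupancy": curve, "ci_low": lo, "ci_high": hi})


# ---------------------------------------------------------------------------
# half-life surplus-binding model


@dataclass
class HalfLifeFit:
    a: float            # surplus binding per unit half-life
    b: float            # baseline binding on intact transcripts
    ratio: float        # a / b
    a_ci: tuple[float, float]
    b_ci: tuple[float, float]
    ratio_ci: tuple[float, float]
    n: int


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    a = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return a, ym - a * xm


def fit_halflife_model(features: pd.DataFrame,
                       occupancy_col: str = "occupancy",
                       halflife_col: str = "halflife", n_boot: int = 1000,
                       ci: float = 0.95,
                       trim_quantiles: tuple[float, float] = (0.05, 0.95),
                       rng: np.random.Generator | None = None) -> HalfLifeFit:
    """Least-squares fit of occupancy = a * t_half + b with bootstrap CIs.

    Half-lives are trimmed to the [5%, 95%] quantile range first.  The a/b
    ratio is reported with a percentile bootstrap interval; an intercept
    whose CI excludes positive values makes the ratio unstable and is
    flagged with a warning.
    """
    idx = quantile_trim(features[halflife_col], *trim_quantiles).index
    sub = features.loc[idx, [halflife_col, occupancy_col]].dropna()
    n = len(sub)
    if n < 20:
        raise TranslationError(f"only {n} transcripts after trimming (need >= 20)")
    x = sub[halflife_col].to_numpy(dtype=float)
    y = sub[occupancy_col].to_numpy(dtype=float)
    a, b = _ols_line(x, y)
    if n_boot > 0:
        rng = rng or np.random.default_rng()
        idxs = rng.integers(0, n, size=(n_boot, n))
        xb, yb = x[idxs], y[idxs]
        xm = xb.mean(axis=1, keepdims=True)
        ym = yb.mean(axis=1, keepdims=True)
        a_b = ((xb - xm) * (yb - ym)).sum(axis=1) / ((xb - xm) ** 2).sum(axis=1)
        b_b = ym[:, 0] - a_b * xm[:, 0]
        alpha = (1.0 - ci) / 2.0
        a_ci = tuple(np.quantile(a_b, [alpha, 1 - alpha]))
        b_ci = tuple(np.quantile(b_b, [alpha, 1 - alpha]))
        with np.errstate(divide="ignore", invalid="ignore"):
            r_b = a_b / b_b
        ratio_ci = tuple(np.quantile(r_b, [alpha, 1 - alpha]))
    else:
        a_ci = (a, a)
        b_ci = (b, b)
        ratio_ci = (np.nan, np.nan)
    if b <= 0 and b_ci[1] < 0:
        log.warning("intercept b <= 0 with CI excluding 0: a/b ratio unstable")
    ratio = a / b if b != 0 else np.inf
    return HalfLifeFit(a=float(a), b=float(b), ratio=float(ratio),
                       a_ci=(float(a_ci[0]), float(a_ci[1])),
                       b_ci=(float(b_ci[0]), float(b_ci[1])),
                       ratio_ci=(float(ratio_ci[0]), float(ratio_ci[1])), n=n)


# ---------------------------------------------------------------------------
# likelihood-ratio feature significance


def feature_significance(features: pd.DataFrame,
                         occupancy_col: str = "occupancy_per_nt",
                         feature_cols: tuple[str, ...] = FEATURES,
                         trim_quantiles: tuple[float, float] = (0.05, 0.95),
                         log_transform: tuple[str, ...] = (),
                         max_condition: float = 1e8) -> pd.DataFrame:
    """Per-feature likelihood-ratio p-values for the occupancy regression.

    Transcripts are restricted to the intersection of per-feature [5%, 95%]
    quantile ranges (complete cases).  The full Gaussian linear model of
    per-nucleotide occupancy on all features is compared against each
    single-feature-deleted model; the LRT statistic is referred to a
    chi-squared distribution with 1 degree of freedom.  The coefficient
    sign from the full model gives the direction of the correlation.
    """
    df = features[list(feature_cols) + [occupancy_col]].dropna()
    keep = pd.Series(True, index=df.index)
    for col in feature_cols:
        qlo, qhi = df[col].quantile(list(trim_quantiles))
        keep &= (df[col] >= qlo) & (df[col] <= qhi)
    df = df[keep]
    if len(df) < len(feature_cols) + 2:
        raise TranslationError("too few transcripts after trimming")
    X = df[list(feature_cols)].astype(float).copy()
    for col in log_transform:
        X[col] = np.log(X[col])
    std = (X - X.mean()) / X.std(ddof=0)
    cond = np.linalg.cond(std.to_numpy())
    if not np.isfinite(cond) or cond > max_condition:
        corr = std.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise TranslationError(
            f"collinear features (condition number {cond:.3g}): "
            f"{worst[0]} vs {worst[1]}")
    y = df[occupancy_col].to_numpy(dtype=float)
    full = sm.OLS(y, sm.add_constant(X)).fit()
    rows = []
    for col in feature_cols:
        reduced = sm.OLS(y, sm.add_constant(X.drop(columns=[col]))).fit()
        lr = 2.0 * (full.llf - reduced.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
        rows.append({"feature": col, "coefficient": float(full.params[col]),
                     "sign": int(np.sign(full.params[col])), "p_value": p})
    return pd.DataFrame(rows).set_index("feature")
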
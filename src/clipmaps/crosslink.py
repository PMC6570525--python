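"""Cross-link site tables: replicate merging, filtering and occupancy.

A cross-link site is a genomic T (on the read strand) with an observed count
of T->C transition reads (k), total read coverage (n) and a site-level
p-value attached by the upstream preprocessing tool.  Occupancy at a site is
the transition count divided by the RNA concentration at that position in an
input-library control, capped at a high quantile to tame outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "strand", "transitions", "coverage", "p_value"]
_KEY = ["chrom", "pos", "strand"]


class CrosslinkError(ValueError):
    pass


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=str),
        "transitions": pd.Series(dtype=np.int64),
        "coverage": pd.Series(dtype=np.int64),
        "p_value": pd.Series(dtype=float),
    })


def _validate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    missing = set(SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise CrosslinkError(f"site table missing columns {sorted(missing)}")
    if len(sites):
        if (sites["transitions"] < 0).any() or \
                (sites["transitions"] > sites["coverage"]).any():
            raise CrosslinkError("require 0 <= transitions <= coverage")
        if ((sites["p_value"] < 0) | (sites["p_value"] > 1)).any():
            raise CrosslinkError("p_value outside [0, 1]")
        if sites.duplicated(_KEY).any():
            raise CrosslinkError("duplicate (chrom, pos, strand) in site table")
    return sites.reset_index(drop=True)


@dataclass
class FactorDataset:
    """Cross-link sites of one factor (one replicate, or merged)."""

    factor: str
    sites: pd.DataFrame = field(default_factory=_empty_sites)
    replicate: str = "merged"

    def __post_init__(self) -> None:
        self.sites = _validate_sites(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def has_occupancy(self) -> bool:
        return "occupancy" in self.sites.columns

    def with_sites(self, sites: pd.DataFrame) -> "FactorDataset":
        return FactorDataset(self.factor, sites.reset_index(drop=True),
                             self.replicate)

    # -- dense helpers (used by metagene / co-localization) -----------------

    def occupancy_arrays(self, chrom_lengths: dict[str, int]
                         ) -> dict[tuple[str, str], np.ndarray]:
        """Dense per-(chrom, strand) occupancy tracks."""
        if not self.has_occupancy:
            raise CrosslinkError(f"{self.factor}: occupancies not computed")
        arrays = {(c, s): np.zeros(n)
                  for c, n in chrom_lengths.items() for s in ("+", "-")}
        for (chrom, strand), grp in self.sites.groupby(["chrom", "strand"],
                                                       sort=False):
            arr = arrays.get((chrom, strand))
            if arr is not None:
                arr[grp["pos"].to_numpy()] = grp["occupancy"].to_numpy()
        return arrays

    @classmethod
    def from_tsv(cls, path, factor: str, replicate: str = "merged"
                 ) -> "FactorDataset":
        df = pd.read_csv(path, sep="\t")
        return cls(factor, df, replicate)

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)


class InputControl:
    """Background RNA concentration track from the non-IP input library.

    Holds, per (chrom, pos, strand), the read coverage and the fraction of
    reads carrying the T->C transition (used to flag strain SNPs).
    """

    def __init__(self, track: pd.DataFrame) -> None:
        missing = {"chrom", "pos", "strand", "coverage",
                   "transition_fraction"} - set(track.columns)
        if missing:
            raise CrosslinkError(f"control track missing columns {sorted(missing)}")
        if len(track) and (track["coverage"] < 0).any():
            raise CrosslinkError("control coverage must be nonnegative")
        self.track = track.reset_index(drop=True)
        self._indexed = track.set_index(_KEY)[["coverage", "transition_fraction"]]
        if self._indexed.index.has_duplicates:
            raise CrosslinkError("duplicate positions in control track")

    def __len__(self) -> int:
        return len(self.track)

    def lookup(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Coverage and transition fraction aligned to `sites` rows.

        Positions absent from the control get coverage 0 and NaN fraction.
        """
        idx = pd.MultiIndex.from_frame(sites[_KEY])
        out = self._indexed.reindex(idx)
        out["coverage"] = out["coverage"].fillna(0.0)
        return out.reset_index(drop=True)

    def coverage_at(self, chrom: str, pos: int, strand: str) -> float:
        try:
            return float(self._indexed.at[(chrom, pos, strand), "coverage"])
        except KeyError:
            return 0.0

    @classmethod
    def from_tsv(cls, path) -> "InputControl":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.track.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations


def merge_replicates(datasets: list[FactorDataset]) -> FactorDataset:
    """Merge replicate site tables by summing counts per position.

    Transition and coverage counts are added across replicates; a merged
    site carries the minimum replicate p-value (the upstream tool's pooled
    re-evaluation is out of scope).
    """
    if not datasets:
        raise CrosslinkError("no datasets to merge")
    factors = {d.factor for d in datasets}
    if len(factors) != 1:
        raise CrosslinkError(f"cannot merge different factors: {sorted(factors)}")
    frames = [d.sites for d in datasets if len(d.sites)]
    if not frames:
        return FactorDataset(datasets[0].factor, _empty_sites())
    allsites = pd.concat(frames, ignore_index=True)
    merged = (allsites.groupby(_KEY, as_index=False, sort=True)
              .agg(transitions=("transitions", "sum"),
                   coverage=("coverage", "sum"),
                   p_value=("p_value", "min")))
    return FactorDataset(datasets[0].factor, merged)


def filter_high_confidence(dataset: FactorDataset, p_max: float = 0.005,
                           min_coverage: int = 2) -> FactorDataset:
    """Keep sites with p_value <= p_max and coverage >= min_coverage."""
    s = dataset.sites
    keep = (s["p_value"] <= p_max) & (s["coverage"] >= min_coverage)
    log.info("%s: high-confidence filter kept %d/%d sites",
             dataset.factor, int(keep.sum()), len(s))
    return dataset.with_sites(s[keep])


def snp_filter(dataset: FactorDataset, input_control: InputControl,
               max_fraction: float = 0.75) -> FactorDataset:
    """Drop sites at positions that look like strain SNPs.

    A position where at least `max_fraction` of control-library reads carry
    the same transition is a single-nucleotide polymorphism of the strain,
    not a cross-link.  Positions without control coverage are untouched.
    """
    s = dataset.sites
    if not len(s):
        return dataset
    ctrl = input_control.lookup(s)
    frac = ctrl["transition_fraction"].to_numpy()
    covered = ctrl["coverage"].to_numpy() > 0
    is_snp = covered & ~np.isnan(frac) & (frac >= max_fraction)
    log.info("%s: SNP filter removed %d/%d sites",
             dataset.factor, int(is_snp.sum()), len(s))
    return dataset.with_sites(s[~is_snp])


def compute_occupancy(dataset: FactorDataset, input_control: InputControl,
                      cap_quantile: float = 0.95) -> FactorDataset:
    """Attach occupancy = transitions / control concentration, capped.

    Sites with zero control coverage have an undefined ratio and are dropped
    (count logged).  Occupancies above the empirical `cap_quantile` quantile
    (linear interpolation between order statistics) are replaced by that
    quantile value; order statistics below the cap are unchanged.
    """
    s = dataset.sites
    if not len(s):
        out = s.copy()
        out["input_coverage"] = pd.Series(dtype=float)
        out["occupancy"] = pd.Series(dtype=float)
        return dataset.with_sites(out)
    ctrl = input_control.lookup(s)
    cov = ctrl["coverage"].to_numpy(dtype=float)
    keep = cov > 0
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("%s: dropped %d/%d sites with zero input-control coverage",
                 dataset.factor, n_drop, len(s))
    out = s[keep].copy()
    out["input_coverage"] = cov[keep]
    occ = out["transitions"].to_numpy(dtype=float) / out["input_coverage"].to_numpy()
    if len(occ):
        cap = float(np.quantile(occ, cap_quantile))
        occ = np.minimum(occ, cap)
    out["occupancy"] = occ
    return dataset.with_sites(out)


def transcript_total_occupancies(dataset: FactorDataset, annotation_set
                                 ) -> pd.Series:
    """Total occupancy per annotated transcript (strand-aware).

    A site overlapping several same-strand transcripts contributes to each.
    Transcripts without sites get 0.
    """
    if not dataset.has_occupancy:
        raise CrosslinkError(f"{dataset.factor}: occupancies not computed")
    totals = dict.fromkeys((t.id for t in annotation_set.transcripts), 0.0)
    s = dataset.sites
    for chrom, pos, strand, occ in zip(s["chrom"], s["pos"], s["strand"],
                                       s["occupancy"]):
        for t in annotation_set.transcripts_at(chrom, int(pos), strand):
            totals[t.id] += occ
    return pd.Series(totals, name=dataset.factor)


def replicate_correlation(dataset_a: FactorDataset, dataset_b: FactorDataset,
                          annotation_set) -> float:
    """Spearman correlation of per-transcript occupancies of two replicates."""
    occ_a = transcript_total_occupancies(dataset_a, annotation_set)
    occ_b = transcript_total_occupancies(dataset_b, annotation_set)
    if (occ_a > 0).sum() < 3 or (occ_b > 0).sum() < 3:
        raise CrosslinkError(
            "fewer than 3 transcripts with nonzero occupancy in a replicate")
    rho, _ = stats.spearmanr(occ_a.to_numpy(), occ_b.to_numpy())
    return float(rho)
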
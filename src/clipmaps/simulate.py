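"""Synthetic genomes, annotations, control tracks and cross-link datasets.

The generator emulates the statistical structure the analysis stages
assume: strand-specific cross-link sites whose transition counts follow
factor-specific transcript-class preferences, positional profiles along
transcripts, sequence-motif preferences, and half-life-coupled surplus
binding over a simulated input-control coverage track, with site p-values.
Every quantity carries a ground-truth record so planted signals can be
checked downstream.  All randomness flows through numpy Generators seeded
from the configuration, so identical configurations give byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotations import (AnnotationSet, GenomeSequence, Segment, Transcript,
                          segment_mrna)
from .crosslink import FactorDataset, InputControl
from .translation import SENSE_CODONS, STOP_CODONS

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
DEFAULT_BASE_FREQS = {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31}

#: transcript counts per class, study proportions scaled down ~30x
DEFAULT_CLASS_COUNTS = {"mRNA": 120, "rRNA": 2, "tRNA": 12, "snoRNA": 8,
                        "snRNA": 3, "SUT": 10, "CUT": 14, "NUT": 8}

_NC_LENGTHS = {  # (min, max) lengths of simulated ncRNAs
    "rRNA": (1500, 3500), "tRNA": (70, 100), "snoRNA": (90, 300),
    "snRNA": (100, 300), "SUT": (200, 800), "CUT": (150, 600),
    "NUT": (150, 600),
}


class SimulationError(ValueError):
    pass


@dataclass
class PositionalProfile:
    """Distribution of site offsets in transcript coordinates.

    kind: "uniform" over the transcript; "gaussian" around `center`
    relative to the anchor ("tss" or "pa"; negative = towards 5');
    "exponential_5p" decaying from the TSS with scale `scale`.
    """

    kind: str = "uniform"
    anchor: str = "pa"
    center: float = -100.0
    sd: float = 30.0
    scale: float = 200.0


@dataclass
class FactorSpec:
    name: str
    n_sites: int = 2000
    class_preference: dict[str, float] = field(
        default_factory=lambda: {"mRNA": 1.0})
    positional_profile: PositionalProfile = field(
        default_factory=PositionalProfile)
    motif_preference: tuple[str, int, float] | None = None  # (kmer, offset, frac)
    halflife_coupling: tuple[float, float] | None = None    # (a, b)
    antisense_fraction: float = 0.0
    #: antisense background sites spread over the gene plus this many
    #: flanking nt on each side (pervasive upstream/antisense transcription)
    antisense_span_extension: int = 700
    decoy_fraction: float = 0.2
    noise: float = 0.4          # lognormal sd of per-site occupancy noise
    dispersion: float = 5.0     # negative-binomial shape for transitions
    occupancy_scale: float = 2.0
    transcript_weights: dict[str, float] | None = None  # explicit preference

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise SimulationError("n_sites must be positive")
        if any(w < 0 for w in self.class_preference.values()) or \
                not any(self.class_preference.values()):
            raise SimulationError("class weights must be >= 0, not all zero")
        for frac in (self.antisense_fraction, self.decoy_fraction):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError("fractions must lie in [0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chrI": 260_000, "chrII": 260_000,
                                 "chrIII": 180_000})
    base_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_FREQS))
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    isolated_fraction: float = 1.0   # fraction of mRNAs with clean flanks
    isolated_gap: int = 1600         # gap guaranteeing metagene eligibility
    crowded_gap: int = 200
    utr5_range: tuple[int, int] = (30, 150)
    utr3_range: tuple[int, int] = (50, 250)
    cds_codon_range: tuple[int, int] = (400, 800)
    intron_probability: float = 0.05
    intron_length_range: tuple[int, int] = (60, 300)
    #: correlation among (optimality, expression, halflife) via Gaussian copula
    feature_correlation: list[list[float]] = field(
        default_factory=lambda: np.eye(3).tolist())
    halflife_lognorm: tuple[float, float] = (np.log(15.0), 0.6)  # minutes
    expression_lognorm: tuple[float, float] = (2.0, 1.0)         # reads/base
    optimality_range: tuple[float, float] = (0.2, 0.9)
    control_depth: float = 20.0
    control_noise: float = 0.3
    #: pervasive-transcription background on the antisense strand, as a
    #: fraction of sense coverage (gives antisense sites a defined occupancy)
    control_antisense_fraction: float = 0.1
    #: length of gene-flanking regions that receive background coverage on
    #: both strands (pervasive transcription around genes)
    control_flank: int = 800
    n_snps: int = 10


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> GenomeSequence:
    """i.i.d. random genome at the configured base frequencies."""
    rng = rng or np.random.default_rng(config.seed)
    freqs = config.base_freqs
    p = np.array([freqs[b] for b in "ACGT"], dtype=float)
    p = p / p.sum()
    chroms = {}
    for name, size in config.chrom_sizes.items():
        if size <= 0:
            raise SimulationError(f"chromosome {name!r} size must be > 0")
        chroms[name] = "".join(BASES[rng.choice(4, size=size, p=p)])
    return GenomeSequence(chroms)


# ---------------------------------------------------------------------------
# annotations + transcript features


def _gaussian_copula(rng: np.random.Generator, corr: np.ndarray,
                     n: int) -> np.ndarray:
    """Uniform marginals with the given Gaussian-copula correlation."""
    corr = np.asarray(corr, dtype=float)
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-8:
        raise SimulationError("feature correlation matrix not positive "
                              "semi-definite")
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr)))
    z = rng.standard_normal((n, len(corr))) @ chol.T
    from scipy.stats import norm
    return norm.cdf(z)


def _remove_inframe_stops(seq: bytearray, start: int, end: int, strand: str,
                          rng: np.random.Generator) -> None:
    """Rewrite in-frame stop codons in [start, end) to random sense codons."""
    sense = np.array(SENSE_CODONS)
    if strand == "+":
        for i in range(start, end, 3):
            codon = seq[i:i + 3].decode()
            if codon in STOP_CODONS:
                seq[i:i + 3] = rng.choice(sense).encode()
    else:
        from .annotations import reverse_complement
        for i in range(end - 3, start - 1, -3):
            codon = reverse_complement(seq[i:i + 3].decode())
            if codon in STOP_CODONS:
                repl = reverse_complement(str(rng.choice(sense)))
                seq[i:i + 3] = repl.encode()


def simulate_annotations(genome: GenomeSequence, config: SimulationConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[AnnotationSet, pd.DataFrame]:
    """Place transcripts on the genome and draw per-transcript features.

    mRNAs get utr5/cds/utr3 segments (CDS length divisible by 3, in-frame
    stop codons rewritten away) and optionally one intron; ncRNA classes are
    interleaved.  An `isolated_fraction` of mRNAs receives flanking gaps
    large enough to pass the metagene neighbor filters.  Features
    (optimality, expression, half-life) follow a Gaussian copula with the
    configured correlation matrix, mapped to positive marginal scales.
    Returns the annotation set and the feature table.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    genome_mut = {name: bytearray(seq, "ascii")
                  for name, seq in genome.chroms.items()}
    jobs: list[tuple[str, int]] = []  # (class, approx length placeholder)
    for cls, count in config.class_counts.items():
        jobs += [(cls, i) for i in range(count)]
    rng.shuffle(jobs)

    chrom_names = list(config.chrom_sizes)
    cursors = {name: 100 for name in chrom_names}
    transcripts: list[Transcript] = []
    counters = {cls: 0 for cls in config.class_counts}
    n_mrna = config.class_counts.get("mRNA", 0)
    n_isolated = int(round(config.isolated_fraction * n_mrna))
    mrna_seen = 0

    for cls, _ in jobs:
        counters[cls] += 1
        tid = f"{cls}_{counters[cls]:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if cls == "mRNA":
            utr5 = int(rng.integers(*config.utr5_range))
            utr3 = int(rng.integers(*config.utr3_range))
            n_codons = int(rng.integers(*config.cds_codon_range))
            cds_len = 3 * n_codons
            has_intron = rng.random() < config.intron_probability
            intron_len = (int(rng.integers(*config.intron_length_range))
                          if has_intron else 0)
            length = utr5 + cds_len + intron_len + utr3
            mrna_seen += 1
            isolated = mrna_seen <= n_isolated
        else:
            length = int(rng.integers(*_NC_LENGTHS[cls]))
            isolated = False
        gap = config.isolated_gap if (cls == "mRNA" and isolated) \
            else config.crowded_gap
        # first chromosome with room
        placed = False
        for chrom in chrom_names:
            start = cursors[chrom] + gap
            end = start + length
            if end + gap < config.chrom_sizes[chrom]:
                cursors[chrom] = end
                placed = True
                break
        if not placed:
            raise SimulationError(
                "transcripts do not fit in the genome; increase chromosome "
                "sizes or reduce class counts")
        t = Transcript(id=tid, chrom=chrom, strand=strand, start=start,
                       end=end, class_label=cls, abundance=1.0)
        if cls == "mRNA":
            if strand == "+":
                cds_start = start + utr5
            else:
                cds_start = start + utr3
            cds_span = (cds_start, cds_start + cds_len + intron_len)
            introns = []
            if intron_len:
                # intron between two codon blocks, inside the CDS span
                ioff = 3 * int(rng.integers(10, n_codons - 10))
                introns = [(cds_start + ioff, cds_start + ioff + intron_len)]
            t = segment_mrna(t, cds_span, introns)
            seqbuf = genome_mut[chrom]
            # rewrite in-frame stops so the spliced frame is a clean ORF;
            # each CDS piece is handled in its phase within the spliced frame
            cds_segs = [s for s in t.segments if s.kind == "cds"]
            cds_segs_genomic = sorted(cds_segs, key=lambda s: s.start)
            if strand == "-":
                cds_segs_genomic = cds_segs_genomic[::-1]
            offset = 0
            for seg in cds_segs_genomic:
                seg_len = seg.end - seg.start
                # align to the reading frame across segments
                lead = (3 - offset % 3) % 3
                if strand == "+":
                    lo = seg.start + lead
                    hi = seg.start + seg_len - (seg_len - lead) % 3
                    if hi - lo >= 3:
                        _remove_inframe_stops(seqbuf, lo, hi, "+", rng)
                else:
                    hi = seg.end - lead
                    lo = seg.end - seg_len + (seg_len - lead) % 3
                    if hi - lo >= 3:
                        _remove_inframe_stops(seqbuf, lo, hi, "-", rng)
                offset += seg_len
        transcripts.append(t)

    genome.chroms = {name: buf.decode("ascii")
                     for name, buf in genome_mut.items()}
    ann = AnnotationSet(transcripts, genome=genome)

    mrna_ids = [t.id for t in ann.mrnas]
    corr = np.asarray(config.feature_correlation, dtype=float)
    u = _gaussian_copula(rng, corr, len(mrna_ids))
    from scipy.stats import norm
    z = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    opt_lo, opt_hi = config.optimality_range
    optimality = opt_lo + (opt_hi - opt_lo) * u[:, 0]
    expression = np.exp(config.expression_lognorm[0]
                        + config.expression_lognorm[1] * z[:, 1])
    halflife = np.exp(config.halflife_lognorm[0]
                      + config.halflife_lognorm[1] * z[:, 2])
    features = pd.DataFrame({
        "transcript_id": mrna_ids,
        "length": [ann[tid].length for tid in mrna_ids],
        "optimality": optimality,
        "expression": expression,
        "halflife": halflife,
    }).set_index("transcript_id")
    return ann, features


# ---------------------------------------------------------------------------
# input control


def simulate_input_control(annotation_set: AnnotationSet,
                           features: pd.DataFrame, config: SimulationConfig,
                           rng: np.random.Generator | None = None
                           ) -> tuple[InputControl, pd.DataFrame]:
    """Background coverage track over transcribed positions, with SNPs.

    Coverage at each transcript position is depth x expression with
    multiplicative lognormal noise; overlapping transcripts add.  A
    configurable number of SNP positions get transition fractions >= 0.75;
    all other positions get near-zero fractions.  Returns the control and a
    table of planted SNP positions.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    anti_frac = config.control_antisense_fraction
    chroms, positions, strands, coverages = [], [], [], []
    # per-transcript expression (ncRNAs drawn here; mRNAs from features)
    for t in annotation_set.transcripts:
        if t.class_label == "mRNA" and t.id in features.index:
            expr = float(features.loc[t.id, "expression"])
        else:
            expr = float(np.exp(config.expression_lognorm[0]
                                + config.expression_lognorm[1]
                                * rng.standard_normal()))
        depth = config.control_depth * expr / np.exp(
            config.expression_lognorm[0])
        noise = np.exp(config.control_noise
                       * rng.standard_normal(t.length)
                       - 0.5 * config.control_noise ** 2)
        cov = depth * noise
        pos = np.arange(t.start, t.end)
        anti = "-" if t.strand == "+" else "+"
        chroms.append(np.repeat(t.chrom, t.length))
        positions.append(pos)
        strands.append(np.repeat(t.strand, t.length))
        coverages.append(cov)
        if anti_frac > 0:
            chroms.append(np.repeat(t.chrom, t.length))
            positions.append(pos)
            strands.append(np.repeat(anti, t.length))
            coverages.append(anti_frac * cov)
        if anti_frac > 0 and config.control_flank > 0:
            # pervasive background around the gene, both strands
            chrom_len = len(annotation_set.genome.chroms[t.chrom]) \
                if annotation_set.genome else t.end + config.control_flank
            lo = max(t.start - config.control_flank, 0)
            hi = min(t.end + config.control_flank, chrom_len)
            fpos = np.concatenate([np.arange(lo, t.start),
                                   np.arange(t.end, hi)])
            if len(fpos):
                fcov = anti_frac * depth * np.exp(
                    config.control_noise * rng.standard_normal(len(fpos))
                    - 0.5 * config.control_noise ** 2)
                for st in ("+", "-"):
                    chroms.append(np.repeat(t.chrom, len(fpos)))
                    positions.append(fpos)
                    strands.append(np.repeat(st, len(fpos)))
                    coverages.append(fcov)
    flat = pd.DataFrame({
        "chrom": np.concatenate(chroms),
        "pos": np.concatenate(positions),
        "strand": np.concatenate(strands),
        "coverage": np.concatenate(coverages),
    })
    track = (flat.groupby(["chrom", "pos", "strand"], as_index=False,
                          sort=True)["coverage"].sum())
    track["transition_fraction"] = rng.beta(1.0, 300.0, size=len(track))
    snp_idx = rng.choice(len(track), size=min(config.n_snps, len(track)),
                         replace=False)
    track.loc[snp_idx, "transition_fraction"] = rng.uniform(
        0.75, 1.0, size=len(snp_idx))
    snps = track.iloc[sorted(snp_idx)][["chrom", "pos", "strand"]].reset_index(
        drop=True)
    return InputControl(track), snps


# ---------------------------------------------------------------------------
# motif planting


def plant_motif(genome: GenomeSequence, chrom: str, pos: int, strand: str,
                kmer: str, offset: int) -> None:
    """Write `kmer` starting at transcript-strand offset `offset` from a site.

    Offsets are in reading orientation of `strand`; the cross-linked T at
    offset 0 is never overwritten (the k-mer base there must be T anyway
    for the cell to be feasible).
    """
    from .annotations import reverse_complement
    seq = bytearray(genome.chroms[chrom], "ascii")
    if strand == "+":
        for j, base in enumerate(kmer):
            gpos = pos + offset + j
            if gpos == pos:
                continue
            seq[gpos] = ord(base)
    else:
        for j, base in enumerate(kmer):
            gpos = pos - (offset + j)
            if gpos == pos:
                continue
            seq[gpos] = ord(reverse_complement(base))
    genome.chroms[chrom] = seq.decode("ascii")


# ---------------------------------------------------------------------------
# factor datasets


def _nearest_t(seq: str, pos: int, strand: str, lo: int, hi: int) -> int | None:
    """Nearest position in [lo, hi) whose strand-sense base is T."""
    target = "T" if strand == "+" else "A"
    for delta in range(0, hi - lo):
        for cand in (pos - delta, pos + delta):
            if lo <= cand < hi and seq[cand] == target:
                return cand
    return None


def simulate_factor(spec: FactorSpec, annotation_set: AnnotationSet,
                    genome: GenomeSequence, input_control: InputControl,
                    seed: int, features: pd.DataFrame | None = None,
                    snp_sites: pd.DataFrame | None = None
                    ) -> tuple[FactorDataset, dict]:
    """Cross-link sites for one factor with planted, recoverable structure.

    Transcripts are drawn with probability proportional to class weight
    (times a * t_half + b for mRNAs under half-life coupling, or an
    explicit per-transcript weight vector); site offsets follow the
    positional profile and are snapped to the nearest strand-sense T.
    Transition counts are negative-binomial around planted occupancy x
    control concentration; planted sites carry p < 0.005, decoys carry
    p > 0.005 or coverage 1 to exercise the filters.  When a motif
    preference is set, the stated fraction of sites has the k-mer written
    into the genome at the stated offset.  Returns the dataset and a
    ground-truth record.
    """
    rng = np.random.default_rng(seed)
    transcripts = annotation_set.transcripts
    weights = np.zeros(len(transcripts))
    for i, t in enumerate(transcripts):
        w = spec.class_preference.get(t.class_label, 0.0)
        if spec.transcript_weights is not None:
            w *= spec.transcript_weights.get(t.id, 0.0)
        elif spec.halflife_coupling is not None and t.class_label == "mRNA" \
                and features is not None and t.id in features.index:
            a, b = spec.halflife_coupling
            w *= max(a * float(features.loc[t.id, "halflife"]) + b, 0.0)
        weights[i] = w
    if weights.sum() <= 0:
        raise SimulationError(f"{spec.name}: no transcript has positive weight")
    probs = weights / weights.sum()

    n_planted = int(round(spec.n_sites * (1.0 - spec.decoy_fraction)))
    n_decoy = spec.n_sites - n_planted
    prof = spec.positional_profile

    def draw_position(t: Transcript) -> tuple[int, str] | None:
        sign = 1 if t.strand == "+" else -1
        if prof.kind == "uniform":
            gpos = int(rng.integers(t.start, t.end))
        elif prof.kind == "gaussian":
            anchor = t.pa_site if prof.anchor == "pa" else t.tss
            off = rng.normal(prof.center, prof.sd)
            gpos = int(round(anchor + sign * off))
        elif prof.kind == "exponential_5p":
            off = rng.exponential(prof.scale)
            gpos = int(round(t.tss + sign * off))
        else:
            raise SimulationError(f"unknown profile kind {prof.kind!r}")
        gpos = int(np.clip(gpos, t.start, t.end - 1))
        strand = t.strand
        lo, hi = t.start, t.end
        if rng.random() < spec.antisense_fraction:
            strand = "-" if strand == "+" else "+"
            ext = spec.antisense_span_extension
            lo = max(t.start - ext, 0)
            hi = min(t.end + ext, len(genome.chroms[t.chrom]))
            gpos = int(rng.integers(lo, hi))  # diffuse background placement
        snapped = _nearest_t(genome.chroms[t.chrom], gpos, strand, lo, hi)
        if snapped is None:
            return None
        return snapped, strand

    snp_keys = set()
    if snp_sites is not None:
        snp_keys = {(r.chrom, int(r.pos), r.strand)
                    for r in snp_sites.itertuples()}

    chosen = rng.choice(len(transcripts), size=n_planted, p=probs)
    site_rows: dict[tuple[str, int, str], dict] = {}
    motif_sites: list[tuple[str, int, str]] = []
    want_motif = 0
    if spec.motif_preference is not None:
        want_motif = int(round(spec.motif_preference[2] * n_planted))

    # per-site occupancy has a constant mean so a transcript's TOTAL
    # occupancy stays proportional to its planted weight (site counts carry
    # the preference); this keeps the surplus-binding relation linear
    occ_mean = spec.occupancy_scale
    for ti in chosen:
        t = transcripts[ti]
        drawn = draw_position(t)
        if drawn is None:
            continue
        gpos, strand = drawn
        key = (t.chrom, gpos, strand)
        if key in snp_keys:
            continue
        occ = occ_mean * np.exp(
            spec.noise * rng.standard_normal() - 0.5 * spec.noise ** 2)
        cov = input_control.coverage_at(*key)
        mean_k = max(occ * cov, 0.5)
        # negative binomial with shape `dispersion` around mean_k
        shape = spec.dispersion
        lam = rng.gamma(shape, mean_k / shape)
        k = int(rng.poisson(lam))
        k = max(k, 1)
        n_reads = k + int(rng.poisson(0.5 * k))
        n_reads = max(n_reads, 2)  # planted sites must pass the coverage filter
        p_val = float(rng.uniform(0.0, 0.005))
        if spec.motif_preference is not None and len(motif_sites) < want_motif:
            kmer, m_off, _ = spec.motif_preference
            span_lo = gpos - 12
            span_hi = gpos + 12
            if span_lo >= 0 and span_hi < len(genome.chroms[t.chrom]):
                plant_motif(genome, t.chrom, gpos, strand, kmer, m_off)
                motif_sites.append(key)
        prev = site_rows.get(key)
        if prev is None:
            site_rows[key] = {"chrom": key[0], "pos": key[1], "strand": key[2],
                              "transitions": k, "coverage": n_reads,
                              "p_value": p_val, "decoy": False}
        else:
            prev["transitions"] += k
            prev["coverage"] += n_reads
            prev["p_value"] = min(prev["p_value"], p_val)

    # decoys: fail the high-confidence filter (p too large or coverage 1)
    n_half = n_decoy // 2
    made = 0
    attempts = 0
    while made < n_decoy and attempts < 50 * max(n_decoy, 1):
        attempts += 1
        ti = int(rng.choice(len(transcripts), p=probs))
        t = transcripts[ti]
        drawn = draw_position(t)
        if drawn is None:
            continue
        gpos, strand = drawn
        key = (t.chrom, gpos, strand)
        if key in site_rows or key in snp_keys:
            continue
        if made < n_half:
            row = {"chrom": key[0], "pos": key[1], "strand": key[2],
                   "transitions": 1, "coverage": 1,
                   "p_value": float(rng.uniform(0.0, 0.005)), "decoy": True}
        else:
            k = int(rng.integers(1, 4))
            row = {"chrom": key[0], "pos": key[1], "strand": key[2],
                   "transitions": k, "coverage": k + int(rng.integers(1, 5)),
                   "p_value": float(rng.uniform(0.0051, 1.0)), "decoy": True}
        site_rows[key] = row
        made += 1

    # deliberate artifact sites at planted SNP positions: pass every filter
    # except the SNP filter
    for key in sorted(snp_keys):
        if key in site_rows:
            continue
        site_rows[key] = {"chrom": key[0], "pos": key[1], "strand": key[2],
                          "transitions": 5, "coverage": 8,
                          "p_value": float(rng.uniform(0.0, 0.004)),
                          "decoy": False}

    rows = sorted(site_rows.values(),
                  key=lambda r: (r["chrom"], r["pos"], r["strand"]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "transitions",
                                     "coverage", "p_value", "decoy"])
    decoy_keys = [(r["chrom"], r["pos"], r["strand"])
                  for r in rows if r["decoy"]]
    df = df.drop(columns="decoy")
    truth = {
        "factor": spec.name,
        "class_preference": dict(spec.class_preference),
        "positional_profile": asdict(spec.positional_profile),
        "motif_preference": list(spec.motif_preference)
        if spec.motif_preference else None,
        "n_motif_sites": len(motif_sites),
        "halflife_coupling": list(spec.halflife_coupling)
        if spec.halflife_coupling else None,
        "n_planted": n_planted,
        "n_decoys": len(decoy_keys),
        "decoy_sites": [list(k) for k in decoy_keys],
        "snp_sites": [list(k) for k in sorted(snp_keys)],
        "seed": seed,
    }
    return FactorDataset(spec.name, df), truth


# ---------------------------------------------------------------------------
# codon-composition planting


def plant_codon_bias(genome: GenomeSequence, annotation_set: AnnotationSet,
                     transcript_ids: list[str], codon: str,
                     target_fraction: float,
                     rng: np.random.Generator) -> None:
    """Rewrite codons in the given transcripts' CDS toward a target fraction.

    Random sense codons of the reading frame are replaced by `codon` until
    its fraction reaches `target_fraction`; used to plant composition bias
    for codon-enrichment tests.
    """
    from .annotations import reverse_complement
    for tid in transcript_ids:
        t = annotation_set[tid]
        cds = [s for s in t.segments if s.kind == "cds"]
        if len(cds) != 1:
            continue  # skip intron-containing CDS for simplicity
        seg = cds[0]
        seqbuf = bytearray(genome.chroms[t.chrom], "ascii")
        starts = list(range(seg.start, seg.end - 2, 3))
        n_codons = len(starts)
        n_target = int(round(target_fraction * n_codons))
        current = 0
        for s0 in starts:
            c = seqbuf[s0:s0 + 3].decode()
            if t.strand == "-":
                c = reverse_complement(c)
            if c == codon:
                current += 1
        candidates = [s0 for s0 in starts]
        rng.shuffle(candidates)
        for s0 in candidates:
            if current >= n_target:
                break
            c = seqbuf[s0:s0 + 3].decode()
            if t.strand == "-":
                c = reverse_complement(c)
            if c == codon:
                continue
            repl = codon if t.strand == "+" else reverse_complement(codon)
            seqbuf[s0:s0 + 3] = repl.encode()
            current += 1
        genome.chroms[t.chrom] = seqbuf.decode("ascii")


def cds_sequences(annotation_set: AnnotationSet,
                  genome: GenomeSequence) -> dict[str, str]:
    """Spliced CDS sequence (transcript orientation) per mRNA."""
    out = {}
    for t in annotation_set.mrnas:
        cds = [s for s in t.segments if s.kind == "cds"]
        cds.sort(key=lambda s: s.start)
        seq = "".join(genome.chroms[t.chrom][s.start:s.end] for s in cds)
        if t.strand == "-":
            from .annotations import reverse_complement
            seq = reverse_complement(seq)
        out[t.id] = seq
    return out


def random_codon_scores(rng: np.random.Generator) -> dict[str, float]:
    """Synthetic per-codon optimality scores, uniform on [0, 1]."""
    return {c: float(rng.uniform(0.0, 1.0)) for c in SENSE_CODONS}


def write_ground_truth(truths: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(truths, fh, indent=1)
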
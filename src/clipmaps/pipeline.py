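"""Reproducible stage orchestration over the analysis modules.

A run is driven by a single configuration (YAML or dict): synthetic inputs
are generated or existing files loaded, then the requested stages execute
in dependency order, writing TSV/JSON artifacts and a manifest into the
output directory.  All stage parameters default to the study's values
(p <= 0.005, coverage >= 2, SNP fraction 75%, occupancy cap 95th
percentile, metagene window +-700 nt / min length 1500 / smoothing 41 /
1500 bootstrap iterations, co-localization window +-40 nt, motif site cap
5000, background base probabilities 0.31/0.19).  Reruns with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import class_enrichment as ce
from . import cooccupancy as co
from . import crosslink as cx
from . import metagene as mg
from . import motifs as mo
from . import simulate as sim
from . import translation as tr
from .annotations import AnnotationSet, GenomeSequence, load_annotations, \
    write_annotations

log = logging.getLogger(__name__)

STAGES = ("simulate", "sites", "class_enrich", "metagene", "cooccupancy",
          "colocalize", "codon", "halflife", "regress", "motif")


class ConfigError(ValueError):
    pass


@dataclass
class StageParams:
    """All tunable stage parameters with the study's defaults."""

    p_max: float = 0.005
    min_coverage: int = 2
    snp_max_fraction: float = 0.75
    cap_quantile: float = 0.95
    metagene_window: int = 700
    metagene_min_length: int = 1500
    metagene_smooth: int = 41
    metagene_n_boot: int = 1500
    metagene_ci: float = 0.95
    metagene_align_points: tuple[str, ...] = ("TSS", "pA")
    metagene_strand_modes: tuple[str, ...] = ("sense", "antisense")
    coloc_window: int = 40
    coloc_denominator: str = "colrow"
    tsne_perplexity: float = 30.0
    codon_n_boot: int = 1000
    codon_ci: float = 0.90
    trim_quantiles: tuple[float, float] = (0.05, 0.95)
    curve_window_frac: float = 0.10
    curve_n_boot: int = 1000
    curve_ci: float = 0.95
    halflife_n_boot: int = 1000
    motif_max_sites: int = 5000
    motif_k: int = 4
    motif_flank: int = 5
    motif_background: dict = field(
        default_factory=lambda: dict(mo.YEAST_BACKGROUND))
    motif_t_bias_correction: bool = True


@dataclass
class RunConfig:
    output_dir: str = "clipmaps_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    params: StageParams = field(default_factory=StageParams)
    simulation: sim.SimulationConfig | None = None
    factors: list[sim.FactorSpec] = field(default_factory=list)
    inputs: dict = field(default_factory=dict)  # paths when not simulating

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "params" in raw:
            raw["params"] = _build(StageParams, raw["params"], "params")
        if raw.get("simulation") is not None:
            raw["simulation"] = _build(sim.SimulationConfig, raw["simulation"],
                                       "simulation")
        if "factors" in raw:
            specs = []
            for i, f in enumerate(raw["factors"]):
                f = dict(f)
                if "positional_profile" in f:
                    f["positional_profile"] = _build(
                        sim.PositionalProfile, f["positional_profile"],
                        f"factors[{i}].positional_profile")
                if f.get("motif_preference") is not None:
                    f["motif_preference"] = tuple(f["motif_preference"])
                if f.get("halflife_coupling") is not None:
                    f["halflife_coupling"] = tuple(f["halflife_coupling"])
                specs.append(_build(sim.FactorSpec, f, f"factors[{i}]"))
            raw["factors"] = specs
        if "stages" in raw:
            bad = set(raw["stages"]) - set(STAGES)
            if bad:
                raise ConfigError(f"unknown stages: {sorted(bad)}")
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _build(klass, raw: dict, where: str):
    known = {f.name for f in dataclasses.fields(klass)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown keys under {where}: {sorted(unknown)}")
    fixed = {}
    for f in dataclasses.fields(klass):
        if f.name not in raw:
            continue
        v = raw[f.name]
        if isinstance(v, list) and "tuple" in str(f.type):
            v = tuple(v)
        fixed[f.name] = v
    return klass(**fixed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Executes stages in dependency order inside an output directory."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.outdir = Path(config.output_dir)
        self.manifest: dict = {"stages": {}, "seed": config.seed}
        self.genome: GenomeSequence | None = None
        self.annotations: AnnotationSet | None = None
        self.features: pd.DataFrame | None = None
        self.control: cx.InputControl | None = None
        self.raw_datasets: dict[str, cx.FactorDataset] = {}
        self.datasets: dict[str, cx.FactorDataset] = {}
        self.occupancy_table: pd.DataFrame | None = None
        self.codon_scores: dict[str, float] | None = None

    # -- plumbing -----------------------------------------------------------

    def _record(self, stage: str, outputs: list[Path], **params) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p)
                        for p in outputs},
            "params": params,
        }

    def _write_df(self, df: pd.DataFrame, rel: str, index=True) -> Path:
        path = self.outdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        return path

    # -- input loading / simulation -----------------------------------------

    def _load_inputs(self) -> None:
        inputs = self.config.inputs
        missing = [k for k in ("genome_fasta", "annotations_gff3",
                               "control_tsv", "sites")
                   if k not in inputs]
        if missing:
            raise ConfigError(
                f"no simulation configured and inputs missing: {missing}")
        for key in ("genome_fasta", "annotations_gff3", "control_tsv",
                    "features_tsv"):
            if key in inputs and not Path(inputs[key]).exists():
                raise ConfigError(f"input file not found: {inputs[key]}")
        self.genome = GenomeSequence.from_fasta(inputs["genome_fasta"])
        self.annotations = load_annotations(inputs["annotations_gff3"],
                                            self.genome)
        self.control = cx.InputControl.from_tsv(inputs["control_tsv"])
        if "features_tsv" in inputs:
            self.features = pd.read_csv(inputs["features_tsv"], sep="\t",
                                        index_col="transcript_id")
        for factor, paths in inputs["sites"].items():
            reps = [cx.FactorDataset.from_tsv(p, factor, replicate=str(i))
                    for i, p in enumerate(paths)]
            self.raw_datasets[factor] = (reps[0] if len(reps) == 1
                                         else cx.merge_replicates(reps))

    def stage_simulate(self) -> None:
        cfg = self.config.simulation
        if cfg is None:
            self._load_inputs()
            return
        if not self.config.factors:
            raise ConfigError("simulation requires at least one factor spec")
        cfg = dataclasses.replace(cfg, seed=cfg.seed + self.config.seed)
        rng = np.random.default_rng(cfg.seed)
        self.genome = sim.simulate_genome(cfg, rng)
        self.annotations, self.features = sim.simulate_annotations(
            self.genome, cfg, rng)
        self.control, snps = sim.simulate_input_control(
            self.annotations, self.features, cfg, rng)
        truths = []
        for i, spec in enumerate(self.config.factors):
            ds, truth = sim.simulate_factor(
                spec, self.annotations, self.genome, self.control,
                seed=cfg.seed + 1000 + i, features=self.features,
                snp_sites=snps)
            self.raw_datasets[spec.name] = ds
            truths.append(truth)
        self.codon_scores = sim.random_codon_scores(rng)
        self.outdir.mkdir(parents=True, exist_ok=True)
        outputs = []
        gpath = self.outdir / "genome.fasta"
        self.genome.to_fasta(gpath)
        apath = self.outdir / "annotations.gff3"
        write_annotations(self.annotations, apath)
        outputs += [gpath, apath]
        outputs.append(self._write_df(self.features, "features.tsv"))
        cpath = self.outdir / "control.tsv"
        self.control.to_tsv(cpath)
        outputs.append(cpath)
        (self.outdir / "sites").mkdir(exist_ok=True)
        for name, ds in self.raw_datasets.items():
            spath = self.outdir / "sites" / f"{name}.raw.tsv"
            ds.to_tsv(spath)
            outputs.append(spath)
        tpath = self.outdir / "ground_truth.json"
        sim.write_ground_truth(truths, tpath)
        scores = pd.Series(self.codon_scores, name="optimality_score")
        outputs.append(self._write_df(scores.rename_axis("codon").to_frame(),
                                      "codon_scores.tsv"))
        outputs.append(tpath)
        self._record("simulate", outputs, seed=cfg.seed)

    # -- analysis stages -----------------------------------------------------

    def _require(self, *attrs: str) -> None:
        names = {"genome": "simulate", "annotations": "simulate",
                 "control": "simulate", "raw_datasets": "simulate",
                 "datasets": "sites", "occupancy_table": "cooccupancy"}
        for attr in attrs:
            val = getattr(self, attr)
            if val is None or (isinstance(val, dict) and not val):
                raise ConfigError(
                    f"stage requires {attr!r}; run the {names[attr]!r} "
                    f"stage first")

    def stage_sites(self) -> None:
        self._require("raw_datasets", "control")
        p = self.config.params
        outputs = []
        counters = {}
        for name, raw in self.raw_datasets.items():
            hc = cx.filter_high_confidence(raw, p.p_max, p.min_coverage)
            snp = cx.snp_filter(hc, self.control, p.snp_max_fraction)
            occ = cx.compute_occupancy(snp, self.control, p.cap_quantile)
            self.datasets[name] = occ
            counters[name] = {
                "raw": len(raw), "high_confidence": len(hc),
                "after_snp_filter": len(snp), "with_occupancy": len(occ),
            }
            path = self.outdir / "sites" / f"{name}.occupancy.tsv"
            path.parent.mkdir(parents=True, exist_ok=True)
            occ.to_tsv(path)
            outputs.append(path)
        self._record("sites", outputs, p_max=p.p_max,
                     min_coverage=p.min_coverage,
                     snp_max_fraction=p.snp_max_fraction,
                     cap_quantile=p.cap_quantile, counters=counters)

    def stage_class_enrich(self) -> None:
        self._require("datasets", "annotations")
        counts = ce.count_matrix(list(self.datasets.values()),
                                 self.annotations)
        result = ce.enrichment_matrix(counts)
        outputs = [
            self._write_df(result.raw_counts, "class_enrichment/raw_counts.tsv"),
            self._write_df(result.log_counts, "class_enrichment/log2_counts.tsv"),
            self._write_df(result.centered, "class_enrichment/centered.tsv"),
            self._write_df(result.class_cv.to_frame(),
                           "class_enrichment/class_cv.tsv"),
        ]
        self._record("class_enrich", outputs)

    def stage_metagene(self) -> None:
        self._require("datasets", "annotations", "genome")
        p = self.config.params
        lengths = self.genome.lengths
        rng = np.random.default_rng(self.config.seed + 11)
        outputs = []
        for align in p.metagene_align_points:
            for mode in p.metagene_strand_modes:
                transcripts = mg.eligible_transcripts(
                    self.annotations, align, mode, p.metagene_window,
                    p.metagene_min_length)
                if not transcripts:
                    log.warning("no eligible transcripts for %s/%s", align,
                                mode)
                    continue
                profs = {}
                for name, ds in self.datasets.items():
                    clean = mg.exclude_sites_in_regions(ds, self.annotations)
                    profs[name] = mg.average_profile(
                        clean, transcripts, lengths, align, mode,
                        p.metagene_window, p.metagene_smooth,
                        p.metagene_n_boot, p.metagene_ci, rng)
                    outputs.append(self._write_df(
                        profs[name].to_frame(),
                        f"metagene/{name}.{align}.{mode}.tsv", index=False))
                outputs.append(self._write_df(
                    mg.stacked_profiles(profs),
                    f"metagene/stacked.{align}.{mode}.tsv"))
        self._record("metagene", outputs, window=p.metagene_window,
                     min_length=p.metagene_min_length,
                     smooth=p.metagene_smooth, n_boot=p.metagene_n_boot)

    def stage_cooccupancy(self) -> None:
        self._require("datasets", "annotations")
        p = self.config.params
        table = co.transcript_occupancy_table(list(self.datasets.values()),
                                              self.annotations)
        self.occupancy_table = table
        r = co.cooccupancy_matrix(table)
        outputs = [
            self._write_df(table, "cooccupancy/occupancy_table.tsv"),
            self._write_df(r, "cooccupancy/cooccupancy_r.tsv"),
        ]
        if len(r) >= 4:
            coords = co.embed_factors(r, seed=self.config.seed,
                                      perplexity=p.tsne_perplexity)
            outputs.append(self._write_df(coords, "cooccupancy/embedding.tsv"))
        self._record("cooccupancy", outputs)

    def stage_colocalize(self) -> None:
        self._require("datasets", "genome")
        p = self.config.params
        result = co.colocalization(list(self.datasets.values()),
                                   self.genome.lengths, p.coloc_window,
                                   p.coloc_denominator)
        outputs = [
            self._write_df(result.z, "colocalization/z.tsv"),
            self._write_df(result.C, "colocalization/C.tsv"),
            self._write_df(result.R, "colocalization/R.tsv"),
        ]
        self._record("colocalize", outputs, window=p.coloc_window)

    def _transcript_features(self) -> dict[str, pd.DataFrame]:
        if self.occupancy_table is None:
            self._require("datasets", "annotations")
            self.occupancy_table = co.transcript_occupancy_table(
                list(self.datasets.values()), self.annotations)
        if self.features is None:
            raise ConfigError("per-transcript features required (features_tsv "
                              "input or simulation)")
        feats = self.features.copy()
        table = self.occupancy_table
        out = {}
        for factor in table.columns:
            df = feats.copy()
            df["occupancy"] = table[factor].reindex(df.index).fillna(0.0)
            df["occupancy_per_nt"] = df["occupancy"] / df["length"]
            out[factor] = df
        return out

    def stage_codon(self) -> None:
        self._require("datasets", "annotations", "genome")
        if self.occupancy_table is None:
            self.occupancy_table = co.transcript_occupancy_table(
                list(self.datasets.values()), self.annotations)
        p = self.config.params
        seqs = sim.cds_sequences(self.annotations, self.genome)
        fractions = tr.codon_fraction_matrix(seqs)
        rng = np.random.default_rng(self.config.seed + 13)
        outputs = []
        for factor in self.occupancy_table.columns:
            occ = self.occupancy_table[factor]
            occ = occ[occ.index.isin(fractions.index)]
            if occ.sum() <= 0:
                log.warning("%s: zero mRNA occupancy; skipping codon stage",
                            factor)
                continue
            res = tr.codon_enrichment(occ, fractions, p.codon_n_boot,
                                      p.codon_ci, rng)
            outputs.append(self._write_df(
                res.scores, f"codon/{factor}.enrichment.tsv"))
        self._record("codon", outputs, n_boot=p.codon_n_boot, ci=p.codon_ci)

    def stage_halflife(self) -> None:
        p = self.config.params
        per_factor = self._transcript_features()
        rng = np.random.default_rng(self.config.seed + 17)
        fits = {}
        for factor, df in per_factor.items():
            fit = tr.fit_halflife_model(df, n_boot=p.halflife_n_boot,
                                        trim_quantiles=p.trim_quantiles,
                                        rng=rng)
            fits[factor] = {"a": fit.a, "b": fit.b, "a_over_b": fit.ratio,
                            "a_ci": list(fit.a_ci), "b_ci": list(fit.b_ci),
                            "ratio_ci": list(fit.ratio_ci), "n": fit.n}
        path = self.outdir / "halflife_fits.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(fits, indent=1))
        self._record("halflife", [path], n_boot=p.halflife_n_boot)

    def stage_regress(self) -> None:
        p = self.config.params
        per_factor = self._transcript_features()
        rows = []
        for factor, df in per_factor.items():
            sig = tr.feature_significance(df, trim_quantiles=p.trim_quantiles)
            for feature, row in sig.iterrows():
                rows.append({"factor": factor, "feature": feature,
                             "sign": int(row["sign"]),
                             "p_value": row["p_value"]})
        out = pd.DataFrame(rows)
        path = self._write_df(out, "feature_significance.tsv", index=False)
        self._record("regress", [path])

    def stage_motif(self) -> None:
        self._require("datasets", "genome")
        p = self.config.params
        outputs = []
        for name, ds in self.datasets.items():
            top = mo.select_top_sites(ds, p.motif_max_sites)
            windows = mo.extract_windows(top, self.genome, p.motif_k,
                                         p.motif_flank)
            if not windows:
                log.warning("%s: no motif windows; skipping", name)
                continue
            res = mo.kmer_enrichment(windows, p.motif_k, p.motif_background,
                                     p.motif_flank,
                                     t_bias_correction=p.motif_t_bias_correction)
            path = self.outdir / "motifs" / f"{name}.log2_enrichment.tsv"
            path.parent.mkdir(parents=True, exist_ok=True)
            mo.write_enrichment_tsv(res, path)
            outputs.append(path)
        self._record("motif", outputs, max_sites=p.motif_max_sites,
                     k=p.motif_k, t_bias_corrected=p.motif_t_bias_correction)

    # -- driver --------------------------------------------------------------

    def run(self) -> dict:
        order = [s for s in STAGES if s in self.config.stages]
        # analysis stages always need inputs and filtered sites in memory
        if "simulate" not in order:
            order.insert(0, "simulate")
        if "sites" not in order and len(order) > 1:
            order.insert(1, "sites")
        self.outdir.mkdir(parents=True, exist_ok=True)
        for stage in order:
            log.info("running stage %s", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception:
                self.manifest["stages"][stage] = {"failed": True}
                self._finalize()
                raise
        self._finalize()
        return self.manifest

    def _finalize(self) -> None:
        cfg_path = self.outdir / "run_config.yaml"
        cfg_path.write_text(yaml.safe_dump(_serializable(self.config)))
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True))


def _serializable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serializable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run(config: RunConfig) -> dict:
    """Execute a configured pipeline run; returns the manifest."""
    return PipelineRun(config).run()
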
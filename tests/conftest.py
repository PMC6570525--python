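import numpy as np
import pandas as pd
import pytest

from clipmaps import simulate as sim
from clipmaps.annotations import AnnotationSet, GenomeSequence, Transcript, \
    segment_mrna
from clipmaps.crosslink import FactorDataset, InputControl


def make_sites(rows) -> pd.DataFrame:
    """Site table from (chrom, pos, strand, transitions, coverage, p) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "transitions",
                                       "coverage", "p_value"])


@pytest.fixture
def tiny_genome() -> GenomeSequence:
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    return GenomeSequence({
        "chrA": "".join(bases[rng.choice(4, 600, p=[.31, .19, .19, .31])]),
        "chrB": "".join(bases[rng.choice(4, 400, p=[.31, .19, .19, .31])]),
    })


@pytest.fixture
def tiny_annotations(tiny_genome) -> AnnotationSet:
    mrna = segment_mrna(
        Transcript("mRNA_1", "chrA", "+", 50, 350, "mRNA", gene_id="g1",
                   abundance=5.0),
        (100, 301))
    transcripts = [
        mrna,
        Transcript("sno_1", "chrA", "+", 200, 260, "snoRNA"),
        Transcript("trna_1", "chrA", "-", 400, 480, "tRNA"),
        Transcript("cut_1", "chrB", "-", 100, 300, "CUT"),
    ]
    return AnnotationSet(transcripts, genome=tiny_genome)


@pytest.fixture
def flat_control(tiny_genome) -> InputControl:
    rows = []
    for chrom, seq in tiny_genome.chroms.items():
        for strand in "+-":
            for pos in range(len(seq)):
                rows.append((chrom, pos, strand, 10.0, 0.0))
    return InputControl(pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "coverage",
                       "transition_fraction"]))


@pytest.fixture(scope="session")
def small_simulation():
    """A modest end-to-end synthetic dataset shared across tests."""
    cfg = sim.SimulationConfig(
        seed=17,
        chrom_sizes={"chrI": 150_000, "chrII": 120_000},
        class_counts={"mRNA": 30, "tRNA": 6, "snoRNA": 5, "snRNA": 2,
                      "SUT": 5, "CUT": 6, "NUT": 4},
        isolated_fraction=1.0,
    )
    rng = np.random.default_rng(cfg.seed)
    genome = sim.simulate_genome(cfg, rng)
    ann, features = sim.simulate_annotations(genome, cfg, rng)
    control, snps = sim.simulate_input_control(ann, features, cfg, rng)
    return cfg, genome, ann, features, control, snps
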
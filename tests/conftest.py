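import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from soma_pirna import align_annotate as aa
from soma_pirna import synthetic_data as synth
from soma_pirna.intervals import AnnotationTrack


def annotate_cohort(genome: synth.SimGenome, cohort: synth.SimCohort):
    """Align + classify every sample; returns (annotated dict, lib_sizes)."""
    index = aa.GenomeIndex(genome.genome)
    ncrna = AnnotationTrack(genome.ncrna)
    pirna = AnnotationTrack(genome.pirna)
    annotated, lib_sizes = {}, {}
    for sample, reads in cohort.reads.items():
        kept, _ = aa.trim_and_filter(reads)
        aligned = aa.mini_align(kept, index)
        annotated[sample] = aa.classify_reads(aligned, ncrna, pirna)
        lib_sizes[sample] = len(aligned)
    return annotated, lib_sizes


@pytest.fixture(scope="session")
def somatic_cohort():
    """Small two-group somatic-like cohort with four 4x dysregulated loci."""
    cfg = synth.SimConfig(
        seed=11,
        libsize_mean=1500,
        n_pirna_loci=40,
        groups=[
            synth.GroupSpec("control", 5),
            synth.GroupSpec("PD", 5, {f"piR-sim-{i:04d}": 4.0 for i in range(1, 5)}),
        ],
    )
    genome = synth.simulate_genome(cfg)
    cohort = synth.simulate_reads(cfg, genome)
    return cfg, genome, cohort


@pytest.fixture(scope="session")
def somatic_annotated(somatic_cohort):
    cfg, genome, cohort = somatic_cohort
    annotated, lib_sizes = annotate_cohort(genome, cohort)
    return cfg, genome, cohort, annotated, lib_sizes


@pytest.fixture(scope="session")
def germline_cohort():
    cfg = synth.germline_config(seed=13, libsize_mean=1500,
                                groups=[synth.GroupSpec("germline", 3)])
    genome = synth.simulate_genome(cfg)
    cohort = synth.simulate_reads(cfg, genome)
    return cfg, genome, cohort


@pytest.fixture(scope="session")
def germline_annotated(germline_cohort):
    cfg, genome, cohort = germline_cohort
    annotated, lib_sizes = annotate_cohort(genome, cohort)
    return cfg, genome, cohort, annotated, lib_sizes
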
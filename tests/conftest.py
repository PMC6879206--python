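import types

import numpy as np
import pytest

from sisrna import (PipelineConfig, build_reference, default_scenario_bundle,
                    run_pipeline, simulate_compartment_reads)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Full synthetic scenario bundle, simulated once and run end-to-end."""
    d = tmp_path_factory.mktemp("bundle")
    specs = default_scenario_bundle()
    ref = build_reference(specs, 11, d)
    sim = simulate_compartment_reads(ref, 12, d)
    config = PipelineConfig(
        gtf=ref.gtf_path, genome=ref.genome_path,
        sample_sheet=sim.sample_sheet, pas_bed=sim.pas_bed,
        ribo_sample_sheet=sim.ribo_sheet,
        conservation_track=ref.conservation_path,
        unaligned_fastq=sim.fastq_path,
        outdir=str(d / "results"), seed=11)
    result = run_pipeline(config)
    return types.SimpleNamespace(dir=d, specs=specs, ref=ref, sim=sim,
                                 config=config, result=result)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
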
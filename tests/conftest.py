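import pytest

from varconsensus.pipeline import PipelineConfig, run_pipeline
from varconsensus.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """A small simulated cohort (10 patients) with its pipeline run."""
    root = tmp_path_factory.mktemp("cohort10")
    manifest = simulate_cohort(
        SimulationConfig(seed=11, n_patients=10), root / "cohort"
    )
    config = PipelineConfig(
        vcf_dir=str(manifest["vcf_dir"]),
        target_bed=str(manifest["target_bed"]),
        annotation=str(manifest["annotation"]),
        pileup=str(manifest["pileup"]),
        clinical=str(manifest["clinical"]),
        normals_evidence=str(manifest["normals_evidence"]),
        population_af=str(manifest["population_af"]),
        outdir=str(root / "results"),
    )
    result = run_pipeline(config)
    return {"manifest": manifest, "config": config, "result": result}
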
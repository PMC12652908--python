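import pytest

from panfam import synthetic_data as sim
from panfam.pipeline import load_manifest, run_pipeline


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 5-genome synthetic study with planted truth, simulated once."""
    root = tmp_path_factory.mktemp("study")
    cfg = sim.SimConfig(seed=7, n_genomes=5, og_spec=sim.small_og_spec())
    truth = sim.simulate_pan_genome(cfg, root)
    pop_truth = sim.simulate_population(sim.PopConfig(seed=8, n_lines=150),
                                        root)
    counts_truth = sim.simulate_counts(sim.CountsConfig(seed=9), root)
    sim.simulate_signals(truth, root)
    sim.write_manifest(cfg, root)
    return {"dir": root, "config": cfg, "truth": truth,
            "pop_truth": pop_truth, "counts_truth": counts_truth}


@pytest.fixture(scope="session")
def small_run(small_study):
    """The full pipeline run on the 5-genome study."""
    out = small_study["dir"] / "out"
    manifest = load_manifest(small_study["dir"] / "manifest.yaml")
    report = run_pipeline(manifest, out_dir=out, seed=7)
    return {"out": out, "report": report, **small_study}
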
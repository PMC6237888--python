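import pandas as pd
import pytest
from hypothesis import settings

from maillardnet.config import PipelineConfig, SimulationSettings
from maillardnet.pipeline import run_all
from maillardnet.synthetic import generate_reaction_network

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

# single final time point keeps the end-to-end fixtures fast while
# exercising every stage; the time-course behaviour has its own tests
NOISELESS_SIM = dict(
    mass_error_ppm_sd=0.0, noise_peaks=0, time_points_h=(10.0,), replicates=3
)
NOISY_SIM = dict(
    mass_error_ppm_sd=0.1, noise_peaks=40, time_points_h=(10.0,), replicates=3
)


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Full pipeline on a noiseless triplicate simulation (exact masses)."""
    cfg = PipelineConfig(seed=7, simulation=SimulationSettings(**NOISELESS_SIM))
    out = tmp_path_factory.mktemp("noiseless")
    run_all(cfg, out)
    return cfg, out


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    """Full pipeline with 0.1 ppm mass error and noise peaks, seed 42."""
    cfg = PipelineConfig(seed=42, simulation=SimulationSettings(**NOISY_SIM))
    out = tmp_path_factory.mktemp("noisy")
    run_all(cfg, out)
    return cfg, out


def classified_table(out_dir, system: str, time_h: float = 10.0) -> pd.DataFrame:
    return pd.read_csv(
        out_dir / "classified" / f"{system}-t{time_h:g}.csv",
        keep_default_na=False,
    )


def truth_by_system(cfg: PipelineConfig):
    sim = cfg.simulation_config()
    return {
        f"{sim.sugar}-{aa}": generate_reaction_network(sim, aa)
        for aa in sim.amino_acids
    }


def planted_scheme_cores(cfg: PipelineConfig, min_systems: int = 3):
    """Truth-derived expectation for scheme detection: planted pathway cores
    and the systems they occur in, restricted to >= min_systems presence."""
    from maillardnet.classification import ProductClass
    from maillardnet.pathways import AMINO_ACIDS

    per_core: dict = {}
    for system, truth in truth_by_system(cfg).items():
        aa = AMINO_ACIDS[system.split("-")[1]]
        for r in truth:
            if r.pathway is None or r.product_class is not ProductClass.MRP:
                continue
            core = r.formula - aa.side_chain
            per_core.setdefault((core, r.pathway), set()).add(system)
    return {
        key: systems for key, systems in per_core.items()
        if len(systems) >= min_systems
    }
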
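import numpy as np
import pytest

from microtc.design import FactorDecl
from microtc.relations import RatioUniverse
from microtc.synth import Spike, SyntheticDesignSpec, generate_experiment, ice1_like_spec
from microtc.tc import compute_tc_stats, enumerate_tcs


@pytest.fixture(scope="session")
def ice1_experiment():
    """A 2-genotype x 4-cold-duration factorial with a few spiked features."""
    spikes = (
        Spike("g00001", {"cold": "3 hr"}, 1.2),
        Spike("g00001", {"cold": "6 hr"}, 2.0),
        Spike("g00001", {"cold": "24 hr"}, 3.0),
        Spike("g00002", {"genotype": "ice1"}, -1.5),
    )
    return generate_experiment(ice1_like_spec(seed=11, n_features=80, spikes=spikes))


@pytest.fixture(scope="session")
def ice1_tc_tables(ice1_experiment):
    tcs = enumerate_tcs(ice1_experiment.design.sample_sets, ice1_experiment.design.factors)
    return {tc.tc_id: compute_tc_stats(ice1_experiment.matrix, tc) for tc in tcs}


@pytest.fixture(scope="session")
def random_universe():
    """A dense random 20-gene x 15-T/C ratio compendium for oracle tests."""
    rng = np.random.default_rng(42)
    import pandas as pd

    genes = [f"g{i:02d}" for i in range(20)]
    tcs = [f"tc{i:02d}" for i in range(15)]
    log2r = pd.DataFrame(rng.normal(0, 2.5, (20, 15)), index=genes, columns=tcs)
    p = pd.DataFrame(rng.uniform(0, 0.06, (20, 15)), index=genes, columns=tcs)
    return RatioUniverse(log2r, p)


@pytest.fixture
def multi_tc_spec():
    """One 6-level treatment factor giving 5 T/Cs with varying spike sizes."""

    def make(seed=0, n_features=30, pair=None):
        factors = (
            FactorDecl(
                name="treat",
                levels=("none", "t1", "t2", "t3", "t4", "t5"),
                control_level="none",
            ),
        )
        deltas = {"t1": 1.5, "t2": -2.0, "t3": 2.5, "t4": 3.0, "t5": -1.5}
        spikes = tuple(Spike("g00000", {"treat": lvl}, d) for lvl, d in deltas.items())
        spec = SyntheticDesignSpec(factors=factors, n_features=n_features, seed=seed, spikes=spikes)
        if pair is not None:
            from microtc.synth import spike_relations

            spec = spike_relations(spec, [pair], scale=0.9)
        return spec

    return make
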
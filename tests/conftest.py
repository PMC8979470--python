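import numpy as np
import pytest

import meioscope as ms


@pytest.fixture(scope="session")
def table1():
    return ms.load_yakuba_table1()


@pytest.fixture(scope="session")
def x_counts(table1):
    return table1.loc["X"].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def x_fit_mdco(x_counts):
    return ms.fit_tetrad_model(x_counts, model="md_co", compute_ci=False)


@pytest.fixture(scope="session")
def x_fit_pci(x_counts):
    return ms.fit_tetrad_model(x_counts, model="pci", compute_ci=False)


@pytest.fixture(scope="session")
def roundtrip_sim():
    """Simulated cross with well-spaced crossovers plus its called events.

    One 10-Mb arm, strong interference so double crossovers are usually far
    apart, default SNP density.  Shared by the caller-accuracy and
    idempotence tests and by the acceptance suite.
    """
    arm = ms.ArmGeometry("2L", length=10_000_000, detectable_start=300_000,
                         detectable_end=9_700_000, centromere_side="right")
    cfg = ms.SimulationConfig(
        arms=[arm], tetrad_dist=np.array([0.2, 0.5, 0.3, 0.0, 0.0]),
        interference_shape=8.0, n_meioses=1200, seed=20260921)
    truths = ms.simulate_meioses(cfg)
    streams = ms.emit_genotype_streams(truths, cfg)
    genotypes = _frame_to_genotypes(streams)
    events, genotyped, rejections = ms.call_dataset(genotypes, seed=11)
    return {"arm": arm, "config": cfg, "truths": truths,
            "genotypes": genotypes, "events": events,
            "genotyped": genotyped, "rejections": rejections}


def _frame_to_genotypes(df):
    return [
        ms.ChromatidGenotype(cid, arm, grp["pos"].to_numpy(),
                             grp["parent"].to_numpy())
        for (cid, arm), grp in df.groupby(["chromatid_id", "arm"], sort=False)
    ]


@pytest.fixture
def frame_to_genotypes():
    return _frame_to_genotypes
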
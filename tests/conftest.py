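import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trajectory(
    area=None, ccp=None, nucview=None, n=10, valid=None, n_baseline=3
):
    """Hand-built NucleusTrajectory from raw (un-normalized) series."""
    from nucfate.metrics import NucleusTrajectory

    lengths = [len(x) for x in (area, ccp, nucview) if x is not None]
    if lengths:
        n = lengths[0]

    def arr(x, fill):
        if x is None:
            return np.full(n, fill, dtype=float)
        return np.asarray(x, dtype=float)

    area = arr(area, 100.0)
    return NucleusTrajectory(
        time_min=np.arange(n, dtype=float) * 10.0,
        area=area,
        edge_count=arr(ccp, 0.1) * area,
        ccp=arr(ccp, 0.1),
        nucview_mean=arr(nucview, 5.0),
        h2b_mean=np.full(n, 50.0),
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool),
        n_baseline=n_baseline,
    )


@pytest.fixture(scope="session")
def apoptosis_trajectories():
    """Eight measured apoptotic trajectories (shared across tests)."""
    import nucfate as nf

    stacks = nf.generate_replicates(nf.FateProgram.apoptosis(), 8, seed=42)
    trajs = [
        nf.normalize_trajectory(nf.measure_stack(s.h2b, s.nucview)) for s in stacks
    ]
    return stacks, trajs


@pytest.fixture(scope="session")
def stage1_merged():
    """Stage-1 localization table after blinking merge + FWHM filter."""
    import nucfate as nf

    table = nf.generate_localizations(nf.StageProfile.stage(1), 4000, seed=11)
    return nf.filter_by_fwhm(nf.merge_blinking(table))
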
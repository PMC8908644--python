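from datetime import date

import numpy as np
import pytest

import migclass as mc


def make_animal_year(traj: mc.Trajectory, year: int = 2000) -> mc.AnimalYear:
    return mc.AnimalYear(traj.animal_id, year, traj.fixes[0].timestamp.date(),
                         traj.fixes)


def true_origin_fix(traj: mc.Trajectory) -> mc.Fix:
    """The simulator's nominal origin (0,0) with the first fix's timestamp."""
    return mc.Fix(traj.animal_id, traj.fixes[0].timestamp, x=0.0, y=0.0)


@pytest.fixture(scope="session")
def noise_free_trajectories():
    """One noise-free year per deterministic behaviour class."""
    out = {}
    for cat in ("migrant", "mixed_migrant", "resident", "disperser"):
        spec = mc.BehaviourSpec(cat, home_sd_km=0.0)
        traj, truth = mc.simulate_year(spec, 11, animal_id=cat)
        out[cat] = (spec, traj, truth)
    return out
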
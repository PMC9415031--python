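import numpy as np
import pytest

from phycotox.synthetic import SimulationConfig


@pytest.fixture
def noiseless_ojip_config() -> SimulationConfig:
    cfg = SimulationConfig(seed=7)
    cfg.ojip.cv_amplitude = 0.0
    cfg.ojip.cv_phi_p0 = 0.0
    cfg.ojip.cv_vj = 0.0
    cfg.ojip.cv_point = 0.0
    return cfg


@pytest.fixture
def small_config() -> SimulationConfig:
    """Reduced replicate counts for fast end-to-end tests."""
    return SimulationConfig(seed=11, n_ojip=6, n_lif=6, n_pigment=3,
                            n_enzyme=3, n_fa=3, n_mda=3, n_energy=3, n_rlc=4)


def random_cardinal_values(rng: np.random.Generator) -> tuple[float, ...]:
    """A random valid, strictly ordered cardinal-point set F0<F300<FJ<FI<FM."""
    f0 = rng.uniform(200.0, 1000.0)
    incs = rng.uniform(0.05, 1.0, size=4)
    fv = f0 * rng.uniform(1.0, 4.0)
    steps = f0 + fv * np.cumsum(incs) / incs.sum()
    f300, fj, fi, fm = (float(s) for s in steps)
    return f0, f300, fj, fi, fm


def piecewise_transient(f0, f300, fj, fi, fm, sample_id="t", treatment="0"):
    """Monotone piecewise-linear transient through the five cardinal points."""
    from phycotox.ojip import FluorescenceTransient

    knots_t = np.array([10.0, 50.0, 300.0, 2000.0, 30000.0, 300000.0])
    knots_f = np.array([f0, f0, f300, fj, fi, fm])
    t = np.unique(np.concatenate([np.geomspace(10.0, 300000.0, 60), knots_t]))
    return FluorescenceTransient(sample_id, treatment, t, np.interp(t, knots_t, knots_f))
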
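import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from m1dcm.config import default_frequency_grid, default_params
from m1dcm.estimator import SpectralDCM
from m1dcm.forward import SpectralForwardOperator
from m1dcm.model_space import ModelSpec, Population, winning_m1_model
from m1dcm.params import FullParams, NoiseSpec, ObservationParams, SynapticParams

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def winning_model():
    return winning_m1_model()


@pytest.fixture(scope="session")
def grid():
    return default_frequency_grid()


@pytest.fixture(scope="session")
def winning_params(winning_model):
    return default_params(winning_model)


@pytest.fixture(scope="session")
def forward_op(winning_model):
    return SpectralForwardOperator(winning_model)


def make_single_population(kappa=0.25):
    """A decoupled one-population circuit for closed-form oracles."""
    model = ModelSpec(
        name="single",
        populations=(Population.SP,),
        connections=(),
        inputs={"Es": Population.SP},
        architecture_family="custom",
    )
    params = SynapticParams(
        kappa=np.array([kappa]),
        base_strength=np.empty(0),
        gamma=np.empty(0),
        delays=np.empty(0),
    )
    obs = ObservationParams(contributions=np.array([1.0]), gain=1.0)
    noise = NoiseSpec(input_gains=np.array([1.0]))
    return model, FullParams(synaptic=params, observation=obs, noise=noise)


@pytest.fixture(scope="session")
def single_population():
    return make_single_population()


@pytest.fixture(scope="session")
def recovery_study(forward_op):
    """12 synthetic subjects with +-0.3 log-unit perturbations on four key
    connections, each inverted with the generating model.  Shared across
    parameter-recovery and fit-quality tests."""
    model = forward_op.model
    probe = [
        model.connection_index(*e)
        for e in [("SP", "DP"), ("DP", "SP"), ("II", "SP"), ("MP", "II")]
    ]
    rng = np.random.default_rng(2024)
    subjects = []
    for _ in range(12):
        truth = np.zeros(forward_op.layout.size)
        truth[probe] = rng.choice([-0.3, 0.3], size=4)
        data = forward_op.psd(truth) * np.exp(rng.normal(0.0, 0.1, (3, 81)))
        est = SpectralDCM(tol=1e-3, max_iter=256).fit(data)
        subjects.append({"truth": truth, "estimator": est})
    return {"probe": probe, "subjects": subjects}


@pytest.fixture(scope="session")
def model_recovery_study():
    """20 seeded single-subject cohorts generated from the winning model,
    each fitted with the winning model and the reduced CMC."""
    from m1dcm.model_space import CONDITIONS
    from m1dcm.synthetic import default_ground_truth, synth_cohort

    results = []
    for rep in range(20):
        truth = default_ground_truth(seed=10_000 + rep, n_subjects=1)
        cohort = synth_cohort(truth)
        sub = cohort.subjects[0]
        X = np.vstack([sub.spectra[c] for c in CONDITIONS])
        fits = {}
        for name in ("winning_m1", "reduced_cmc"):
            fits[name] = SpectralDCM(model=name, tol=1e-3, max_iter=192).fit(X)
        results.append(fits)
    return results
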
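import numpy as np
import pytest

from msbalipid import BindingModel, TitrationPoint, TitrationSeries, TruthRecord
from msbalipid.binding import predict_abundances


def adair_fractions_reference(ka, l_free):
    """Independent direct-polynomial evaluation of the Adair mole fractions."""
    terms = [l_free ** i * np.prod(ka[:i]) for i in range(len(ka) + 1)]
    total = sum(terms)
    return np.array([t / total for t in terms])


def noiseless_series(kd, p_total, schedule, lipid="KDL", condition="copper-loaded"):
    """Exact (noise-free) titration series for a known K_D vector."""
    model = BindingModel.from_kd(kd)
    points = []
    for l_total in schedule:
        f = predict_abundances(
            model, TitrationPoint(l_total, p_total, (1.0,) + (0.0,) * model.n_max))
        points.append(TitrationPoint(l_total, p_total, tuple(f)))
    return TitrationSeries(points=tuple(points), replicate_id="exact",
                           lipid_name=lipid, condition=condition)


@pytest.fixture
def default_truth():
    return TruthRecord(seed=11)


@pytest.fixture
def exact_series():
    return noiseless_series((0.6, 1.2), 0.3,
                            (0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 1.6, 2.4))
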
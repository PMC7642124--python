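import numpy as np
import pytest

from dicect.pipeline import analyze_study, metrics_from_records
from dicect.profile_model import LineProfile
from dicect.synthetic import demo_specs, generate_study


@pytest.fixture(scope="session")
def noiseless_demo():
    """Noiseless two-species demo study, analysed end to end once.

    Returns (specs, series, ground_truth, records, metrics); shared by the
    synthetic, metrics and acceptance tests to keep the suite fast.
    """
    specs = demo_specs(seed=1, noise_sd=0.0)
    series, gt = generate_study(specs)
    records, failures = analyze_study(series)
    assert not failures, failures
    metrics, mfail = metrics_from_records(records, series)
    assert not mfail, mfail
    return specs, series, gt, records, metrics


@pytest.fixture()
def make_profile():
    """Factory for small ad-hoc profiles used in unit tests."""

    def _make(intensities, length_mm=10.0, **kw):
        y = np.asarray(intensities, dtype=float)
        x = np.linspace(0.0, length_mm, len(y))
        defaults = dict(species="S", specimen_id="X1", slice_index=1,
                        time_h=0.0)
        defaults.update(kw)
        return LineProfile(positions=x, intensities=y, **defaults)

    return _make


def spec_for(specs, rec):
    """Ground-truth spec matching an extracted record's probe."""
    for s in specs:
        if (s.species, s.specimen_id, s.slice_index) == \
                (rec.species, rec.specimen_id, rec.slice_index):
            return s
    raise KeyError(rec.key)
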
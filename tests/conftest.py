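import numpy as np
import pytest

from driftseize.classify import SVMConfig, select_features
from driftseize.dataset import LabelingConfig, label_samples, fit_standardiser
from driftseize.synthetic import SyntheticSpec, generate_feature_stream


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


#: Compact feature-stream geometry used across drift/pipeline tests: four
#: seizures on a 2.5-h independence grid, 60-s epochs, 20-min signature.
COMPACT = dict(
    n_channels=1,
    n_seizures=4,
    interictal_gap_hours=2.5,
    true_sop_minutes=20.0,
    sph_minutes=10.0,
    effect_size=1.5,
    window_length=60.0,
)

COMPACT_LABELING = LabelingConfig(
    sop=20, sph=10, postictal_exclusion=30, independence_gap=0.1
)


def make_training_problem(seed, drift=("none",), n_select=None):
    """Label a compact synthetic patient and standardise its training data.

    Returns (Z_train, y_train, t_train, z_batches, Z_test, y_test) with the
    first three seizures as training batches and the fourth as test.
    """
    from driftseize.dataset import SeizureBatch

    spec = SyntheticSpec(drift=drift, **COMPACT)
    fm, anns = generate_feature_stream(spec, seed=seed)
    batches = label_samples(fm, anns, COMPACT_LABELING)
    train, test = batches[:3], batches[3]
    X = np.vstack([b.features for b in train])
    y = np.concatenate([b.labels for b in train])
    t = np.concatenate([b.epoch_times for b in train])
    std = fit_standardiser(X)
    Z = std.transform(X)
    cols = np.arange(Z.shape[1]) if n_select is None else select_features(Z, y, n_select)
    zb = [
        SeizureBatch(
            seizure_id=b.seizure_id,
            features=std.transform(b.features)[:, cols],
            labels=b.labels,
            epoch_times=b.epoch_times,
            onset=b.onset,
        )
        for b in train
    ]
    return (
        Z[:, cols],
        y,
        t,
        zb,
        std.transform(test.features)[:, cols],
        test.labels,
    )
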
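import numpy as np
import pytest

from hforate.core import Channel, ChannelMap
from hforate.labeling import LabeledObservation
from hforate.rates import FeatureVector


@pytest.fixture
def small_map() -> ChannelMap:
    return ChannelMap(
        [Channel("SOZ00", "SOZ"), Channel("SOZ01", "SOZ"),
         Channel("OUT00", "OUT"), Channel("OUT01", "OUT"),
         Channel("OUT02", "OUT")]
    )


def make_observation(label: str, values, end_s: float = 3600.0,
                     window_len_min: int = 30,
                     seizure_index: int | None = None) -> LabeledObservation:
    fv = FeatureVector(np.asarray(values, dtype=float), end_s, window_len_min)
    return LabeledObservation(fv, label, seizure_index)


def make_dataset(rng, n_pre: int, n_inter: int, informative: int | None = None,
                 shift: float = 2.0):
    """Random 16-feature observations; optionally one informative feature."""
    obs = []
    for i in range(n_pre + n_inter):
        v = rng.standard_normal(16)
        label = "preictal" if i < n_pre else "interictal"
        if informative is not None and label == "preictal":
            v[informative] += shift
        obs.append(
            make_observation(label, v, end_s=1800.0 + 60.0 * i,
                             seizure_index=i if label == "preictal" else None)
        )
    return obs
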
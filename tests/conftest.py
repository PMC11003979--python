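import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from bnct.synthetic import GeneratorConfig  # noqa: E402


def km_oracle(times, events):
    """Brute-force product-limit estimator, independent of the library path.

    Returns (event_times, survival) over the distinct death times: at each
    death time t, S is multiplied by (1 - d_t / n_t) where d_t is the
    number of deaths at t and n_t the number of subjects with time >= t.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    death_times = sorted(set(times[events == 1]))
    s = 1.0
    out_t, out_s = [], []
    for t in death_times:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


@pytest.fixture(scope="session")
def f98_config() -> GeneratorConfig:
    """The packaged F98 study calibration."""
    from importlib import resources

    import yaml

    text = resources.files("bnct.data").joinpath("f98_study.yaml").read_text("utf-8")
    return GeneratorConfig.from_dict(yaml.safe_load(text))
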
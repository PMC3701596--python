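import numpy as np
import pandas as pd
import pytest

from periphsleep import DesignSpec, EffectConfig, ExpressionStudy, generate_study


def make_study(group_values: dict, probe_ids=None) -> ExpressionStudy:
    """Build a study from ``{(tissue, arm, time): per-probe value lists}``.

    ``group_values`` maps a design cell to an array of shape
    (n_probes, n_samples_in_cell).
    """
    blocks, rows = [], []
    animal = 0
    for (tissue, arm, time_h), vals in group_values.items():
        vals = np.atleast_2d(np.asarray(vals, dtype=float))
        for j in range(vals.shape[1]):
            animal += 1
            rows.append({
                "sample_id": f"s{animal:03d}",
                "tissue": tissue,
                "arm": arm,
                "time_h": float(time_h),
                "animal_id": f"a{animal:03d}",
            })
        blocks.append(vals)
    values = np.concatenate(blocks, axis=1)
    if probe_ids is None:
        probe_ids = [f"P{i:03d}" for i in range(values.shape[0])]
    return ExpressionStudy(probe_ids=np.array(probe_ids, dtype=object),
                           samples=pd.DataFrame(rows), values=values)


@pytest.fixture(scope="session")
def small_spec():
    return DesignSpec(n_baseline=4, n_per_group=4, tissues=("heart", "lung"),
                      n_probes=120)


@pytest.fixture(scope="session")
def small_study(small_spec):
    studies, truth = generate_study(small_spec, seed=11)
    return studies, truth


@pytest.fixture(scope="session")
def noiseless_study():
    spec = DesignSpec(n_baseline=3, n_per_group=3, tissues=("heart",),
                      n_probes=40)
    effects = EffectConfig(baseline_sd=0.0, frac_enhanced=0.25,
                           frac_repressed=0.25, frac_var_cluster=0.0)
    studies, truth = generate_study(spec, effects, seed=5)
    return studies["heart"], truth
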
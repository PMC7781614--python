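import numpy as np
import pytest

import capdyn as cd
from capdyn.cohort import ComponentTimeSeries
from capdyn.preprocess import trim_scan, zscore


def make_ts(
    data,
    tr: float = 2.0,
    subject: str = "sub-001",
    noise_flags=None,
    seed_component: str | None = None,
) -> ComponentTimeSeries:
    """Build a ComponentTimeSeries with boilerplate metadata."""
    data = np.asarray(data, dtype=float)
    c = data.shape[1]
    ids = tuple(f"c{j + 1:02d}" for j in range(c))
    return ComponentTimeSeries(
        subject_id=subject,
        data=data,
        tr_seconds=tr,
        component_ids=ids,
        noise_flags=np.zeros(c, bool) if noise_flags is None else noise_flags,
        network_labels=("net",) * c,
        seed_component=ids[0] if seed_component is None else seed_component,
    )


@pytest.fixture(scope="session")
def benchmark_cohort():
    """One benchmark cohort: 40 subjects, 5 planted states, 69 components."""
    return cd.simulate_cohort(cd.CohortConfig(rng_seed=1))


@pytest.fixture(scope="session")
def benchmark_recovery(benchmark_cohort):
    """Trimmed + z-scored series, top-20% pooled frames, k=5 solution and truth.

    This harness isolates the clustering machinery from the temporal
    filters: frame selection and clustering run on the trimmed,
    z-scored synthetic series.
    """
    coh = benchmark_cohort
    proc = [zscore(trim_scan(ts)) for ts in coh.subjects]
    sel = [cd.select_top_frames(ts.seed_series, 0.20, ts.subject_id) for ts in proc]
    pooled = cd.pool_frames(proc, sel)
    sol = cd.kmeans_cluster(pooled, 5, n_init=20, rng_seed=1)
    true = np.array(
        [
            coh.truth.true_labels[sid][f + 5]  # +5: trim offset
            for sid, f in zip(pooled.subject_index, pooled.frame_index)
        ]
    )
    return {"cohort": coh, "processed": proc, "pooled": pooled,
            "solution": sol, "true_labels": true}


@pytest.fixture(scope="session")
def benchmark_pipeline(benchmark_cohort):
    """Fully preprocessed benchmark (trim/detrend/despike/bandpass/z-score)."""
    coh = benchmark_cohort
    proc = [cd.run_postica_pipeline(ts) for ts in coh.subjects]
    sel = [cd.select_top_frames(ts.seed_series, 0.20, ts.subject_id) for ts in proc]
    pooled = cd.pool_frames(proc, sel)
    sol = cd.kmeans_cluster(pooled, 5, n_init=20, rng_seed=1)
    return {"cohort": coh, "processed": proc, "pooled": pooled, "solution": sol}
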
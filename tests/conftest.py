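import numpy as np
import pandas as pd
import pytest

from cryptmeth.io_formats import ProbeTable


def make_probe_table(pooled_means=None, per_probe_values=None, n_control=3, n_case=3,
                     promoter_ids=None, chrom="chr1", spacing=100, width=50):
    """Build a small in-memory probe table.

    Either ``pooled_means`` (every sample gets the same value per probe) or
    ``per_probe_values`` (list of length-(n_control+n_case) vectors) must be
    given.
    """
    if per_probe_values is None:
        per_probe_values = [[m] * (n_control + n_case) for m in pooled_means]
    n = len(per_probe_values)
    if promoter_ids is None:
        promoter_ids = ["promA"] * n
    control = [f"C{i + 1}" for i in range(n_control)]
    case = [f"D{i + 1}" for i in range(n_case)]
    frame = pd.DataFrame(
        {
            "probe_id": [f"P{i + 1}" for i in range(n)],
            "promoter_id": promoter_ids,
            "chrom": [chrom] * n,
            "start": [i * spacing for i in range(n)],
            "end": [i * spacing + width for i in range(n)],
        }
    )
    values = np.asarray(per_probe_values, dtype=float)
    for j, name in enumerate(control + case):
        frame[name] = values[:, j]
    return ProbeTable(frame, {"control": control, "case": case})


@pytest.fixture
def probe_table_factory():
    return make_probe_table


def random_probe_table(rng, n_promoters=50, max_probes=10, n_reps=3):
    """Random small table whose values straddle the filter thresholds."""
    rows_values = []
    promoter_ids = []
    for p in range(n_promoters):
        k = int(rng.integers(1, max_probes + 1))
        for _ in range(k):
            # mixture: some probes clearly enriched, some near zero, some noisy
            center = rng.choice([0.0, 0.25, 0.35, 0.6])
            rows_values.append(center + rng.normal(0, rng.choice([0.05, 0.3]), size=2 * n_reps))
        promoter_ids += [f"prom{p:03d}"] * k
    return make_probe_table(
        per_probe_values=rows_values, promoter_ids=promoter_ids,
        n_control=n_reps, n_case=n_reps,
    )
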
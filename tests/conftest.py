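import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from immunomethyl import synthetic_cohort as sc
from immunomethyl.marker_panel import CELL_TYPES, ReferenceMethylome, build_panel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def ideal_reference(markers_per_type: int = 3, n_opposing: int = 3) -> ReferenceMethylome:
    """Binary-profile reference: planted markers with beta 0.05 / 0.95 exactly."""
    cols = list(CELL_TYPES)
    rows, ids = [], []
    k = 0
    for ct in cols:
        for _ in range(markers_per_type):
            row = {c: 0.95 for c in cols}
            row[ct] = 0.05
            rows.append(row)
            ids.append(f"cg{k:08d}")
            k += 1
    for _ in range(n_opposing):
        row = {c: 0.05 for c in cols}
        row["Neu"] = 0.95
        rows.append(row)
        ids.append(f"cg{k:08d}")
        k += 1
    for _ in range(n_opposing):
        row = {c: 0.05 for c in cols}
        for c in ("NK", "TCD4", "TCD8", "B", "Treg"):
            row[c] = 0.95
        rows.append(row)
        ids.append(f"cg{k:08d}")
        k += 1
    betas = pd.DataFrame(rows, index=pd.Index(ids, name="probe_id"))[cols]
    return ReferenceMethylome(betas)


@pytest.fixture(scope="session")
def rich_reference():
    """Simulated reference with 8 ISUS per subtype (signature-sized panel)."""
    return sc.simulate_reference(n_probes=300, markers_per_type=8, n_opposing=3, seed=11)


@pytest.fixture(scope="session")
def rich_panel(rich_reference):
    return build_panel(rich_reference, k_per_type=8)


@pytest.fixture(scope="session")
def small_cohort(rich_reference):
    """100-pair default-condition cohort shared across statistical tests."""
    cfg = sc.CohortConfig(n_pairs=100, seed=7)
    betas, sheet, truth = sc.simulate_cohort(rich_reference, cfg)
    return betas, sheet, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
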
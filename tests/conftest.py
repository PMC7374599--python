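import numpy as np
import pandas as pd
import pytest

from progsig import CohortConfig, generate_cohort, impute_lod, merge_compartments, normalize_total_protein
from progsig.io import AnalyteTable


def make_table(values, groups=None, compartment="blood", time_week=0, sample_ids=None, analyte_ids=None):
    """Build a minimal AnalyteTable from a raw array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i:03d}_w{time_week}" for i in range(n)]
    analyte_ids = analyte_ids or [f"A{j:03d}" for j in range(p)]
    groups = list(groups) if groups is not None else ["progressor"] * (n // 2) + ["non_progressor"] * (n - n // 2)
    meta = pd.DataFrame(
        {
            "subject_id": [s.split("_")[0] for s in sample_ids],
            "group": groups,
            "time_week": time_week,
            "compartment": compartment,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    analyte_meta = pd.DataFrame({"compartment": compartment}, index=pd.Index(analyte_ids, name="analyte_id"))
    return AnalyteTable(pd.DataFrame(values, index=meta.index, columns=analyte_ids), meta, analyte_meta)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(
        n_prog=30, n_nonprog=20, p_blood=120, p_bal=20, k_signature=20, effect_size=1.5, seed=7
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def merged_week0(small_cohort):
    bal = normalize_total_protein(impute_lod(small_cohort.bal_table, small_cohort.truth.bal_lods))
    return merge_compartments(small_cohort.blood_tables[0], bal)
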
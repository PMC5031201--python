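import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hcpflux import PsmCollection, eight_sample_design, six_sample_design

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def design6():
    return six_sample_design()


@pytest.fixture
def design8():
    return eight_sample_design()


def make_collection(design, rows):
    """Build a PsmCollection from (spectrum_id, peptide, proteins, intensities) tuples.

    *intensities* is a sequence aligned with design.labels.
    """
    table = pd.DataFrame(
        [
            {"spectrum_id": sid, "peptide": pep, "proteins": prot, "score": np.nan,
             **{l: float(v) for l, v in zip(design.labels, vals)}}
            for sid, pep, prot, vals in rows
        ]
    )
    return PsmCollection(design=design, table=table, provenance={"source": "fixture"})


@pytest.fixture
def small_collection(design8):
    """30-PSM fixture over 6 HCPs + 2 product chains; includes shared peptides
    and an all-zero row. Intended for exhaustive-oracle comparisons."""
    rng = np.random.default_rng(42)
    rows = []
    sid = 0
    # proteins P1..P6 with 1..5 unique peptides, 1-2 spectra each
    plan = {"P1": 5, "P2": 4, "P3": 3, "P4": 2, "P5": 1, "P6": 3}
    for acc, n_pep in plan.items():
        for j in range(n_pep):
            for _ in range(1 + (j % 2)):
                vals = rng.lognormal(3, 1, len(design8.labels))
                rows.append((f"s{sid:03d}", f"{acc}PEP{j}", acc, vals))
                sid += 1
    # shared peptides between P1/P2 and P3/P4
    for pair in (("P1", "P2"), ("P3", "P4")):
        vals = rng.lognormal(3, 1, len(design8.labels))
        rows.append((f"s{sid:03d}", f"SHARED{pair[0]}{pair[1]}", ";".join(pair), vals))
        sid += 1
    # all-zero identification-only PSM for P6
    rows.append((f"s{sid:03d}", "P6PEPZ", "P6", np.zeros(len(design8.labels))))
    sid += 1
    # product chains, 4 unique peptides each
    for acc in design8.mab_accessions:
        for j in range(4):
            vals = rng.lognormal(6, 0.5, len(design8.labels))
            rows.append((f"s{sid:03d}", f"{acc}PEP{j}", acc, vals))
            sid += 1
    return make_collection(design8, rows)
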
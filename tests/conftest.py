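import pandas as pd
import pytest

from telomir import datasets
from telomir.simulate import default_config, generate_cohort


def expand_counts(snp_id: str) -> pd.DataFrame:
    """Subject-level table (status, dosage) expanded from bundled genotype counts."""
    rows = []
    for grp, status in (("case", 1), ("control", 0)):
        bb, ab, aa = datasets.GENOTYPE_COUNTS[snp_id][grp]
        rows += [(status, 0)] * bb + [(status, 1)] * ab + [(status, 2)] * aa
    return pd.DataFrame(rows, columns=["status", snp_id])


@pytest.fixture(scope="session")
def default_cohort():
    """One study-default synthetic cohort (307 cases / 320 controls), seed 7."""
    cohort, meta = generate_cohort(default_config(seed=7))
    return cohort


@pytest.fixture(scope="session")
def count_cohorts():
    """Expanded subject-level tables for all five SNPs' published counts."""
    return {sid: expand_counts(sid) for sid in datasets.GENOTYPE_COUNTS}
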
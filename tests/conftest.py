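import io

import numpy as np
import pytest

from epicombo import paper_like_config, read_native, simulate_cohort

TOY_TSV = (
    "sample_id\tphenotype\tsex\trs1982073\n"
    "s1\t1\tM\tTT\n"
    "s2\t0\tF\tCT\n"
)


@pytest.fixture
def toy_dataset():
    return read_native(io.StringIO(TOY_TSV))


@pytest.fixture(scope="session")
def paper_like_cohort():
    """One fixed draw from the default-condition simulator (325 cases / 185 controls)."""
    return simulate_cohort(paper_like_config(), seed=1)


def dataset_from_counts(n11, n10, n01, n00, locus="rsX", carrier_geno="TT", noncarrier_geno="CT"):
    """A dataset whose recessive-TT 2x2 table equals the given counts."""
    rows = (
        [("1", carrier_geno)] * n11
        + [("1", noncarrier_geno)] * n10
        + [("0", carrier_geno)] * n01
        + [("0", noncarrier_geno)] * n00
    )
    text = f"sample_id\tphenotype\tsex\t{locus}\n" + "".join(
        f"s{i}\t{ph}\tNA\t{g}\n" for i, (ph, g) in enumerate(rows)
    )
    return read_native(io.StringIO(text))
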
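import pytest
from hypothesis import HealthCheck, settings

import bipekit as bk

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

#: 34-bp Cre recombinase recognition site used in paired-insertion tests.
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"
ECORV = "GATATC"


@pytest.fixture(scope="session")
def ref400():
    """Toy 400-bp reference with spacer sites nicking exactly at 100 (+)
    and 254 (-)."""
    return bk.make_reference(400, seed=1, pam_anchors=((100, "+"), (254, "-")))


@pytest.fixture(scope="session")
def deletion_design(ref400):
    edit = bk.EditSpec(
        kind="deletion", deletion=bk.GenomicInterval(ref400.seq_id, 100, 254)
    )
    return bk.design_bipe(ref400, edit, "BiPE3", ha_len=12, snap_window=0)


@pytest.fixture(scope="session")
def deletion_alleles(ref400, deletion_design):
    return bk.expected_alleles(deletion_design, ref400.interval(50, 350))
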
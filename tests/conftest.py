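from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pgxledger import generate_keypair
from pgxledger.network import Network

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def keypairs():
    """A small pool of reproducible keypairs shared by read-only tests."""
    return [generate_keypair(seed=1000 + i) for i in range(6)]


@pytest.fixture()
def net():
    return Network(seed=123)


@pytest.fixture()
def clinic(net):
    """A network with one verified patient, pharmacist, physician and
    creator, and one published record covering all guideline drugs."""
    from pgxledger.synth import make_pgx_record, sample_patients

    patient = net.onboard_patient()
    pharmacist = net.onboard_requester("pharmacist")
    physician = net.onboard_requester("physician")
    creator = net.onboard_creator()
    profile = sample_patients(1, np.random.default_rng(5))[0]
    record, recs = make_pgx_record(profile, patient.address, "rec-clinic-1",
                                   np.random.default_rng(6))
    net.publish_record(creator, record, recs)
    return {
        "net": net, "patient": patient, "pharmacist": pharmacist,
        "physician": physician, "creator": creator, "record": record,
        "profile": profile,
    }
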
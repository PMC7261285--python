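import numpy as np
import pytest

from retinaflow.dataset_builder import default_config, sample_record


@pytest.fixture(scope="session")
def small_audit_records():
    """A couple of records per subset at reduced resolution, geometry-clean
    (no degradation, no photometric draws) for flow-fidelity checks."""
    cfg = default_config("main", resolution=(192, 256), n_records=2, seed=11)
    for s in cfg.subsets:
        s.degrade = False
        s.augment_probs = {k: 0.0 for k in s.augment_probs}
        s.double_exposure_prob = 0.0
    return [(spec, sample_record(spec, i))
            for spec in cfg.subsets for i in range(2)]


@pytest.fixture(scope="session")
def tool_record(small_audit_records):
    for spec, rec in small_audit_records:
        if rec.meta["tools"]:
            return rec
    raise RuntimeError("no tool record in audit build")
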
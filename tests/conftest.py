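"""Shared fixtures.

The expensive simulations (static center-out, the training battery) are
session-scoped: several acceptance checks read different statistics off the
same run, exactly as the protocols prescribe.
"""

import numpy as np
import pytest

from reachloop import network as net
from reachloop import protocols as proto
from reachloop.biomech import PlanarArm
from reachloop.engine import Engine, IntegratorConfig


@pytest.fixture(scope="session")
def plant():
    return PlanarArm()


@pytest.fixture(scope="session")
def static_network():
    return net.build("static", seed=1)


@pytest.fixture()
def static_engine(static_network):
    eng = Engine(static_network, IntegratorConfig(seed=1))
    rest_sp = proto.target_to_sp(
        np.asarray(static_network.plant.arm.rest_q), static_network)
    eng.reset(sp=rest_sp)
    return eng


@pytest.fixture(scope="session")
def center_out_static():
    """One full static-network center-out run (48 peripheral reaches)."""
    nw = net.build("static", seed=1)
    eng = Engine(nw, IntegratorConfig(seed=1))
    rest_sp = proto.target_to_sp(np.asarray(nw.plant.arm.rest_q), nw)
    eng.reset(sp=rest_sp)
    res = proto.center_out(eng)
    return nw, res


@pytest.fixture(scope="session")
def training_battery():
    """16-presentation training, 5 seeds per configuration (the heavy one)."""
    out = {}
    for ci, configuration in enumerate(net.CONFIGURATIONS):
        rows = []
        for k in range(5):
            seed = (1000 * (ci + 1) + k * 13 + 7) % 2 ** 31
            eng = Engine(net.build(configuration, seed=seed),
                         IntegratorConfig(seed=seed))
            rows.append(proto.training_phase(eng))
        out[configuration] = rows
    return out


@pytest.fixture(scope="session")
def direction_fields_static():
    def make_engine():
        return Engine(net.build("static", seed=1), IntegratorConfig(seed=1))
    return proto.all_direction_fields(make_engine)
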
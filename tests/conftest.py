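import pytest

from pksdecode.iru import IRU_SEED, decode, decode_iru, iru_bundle, iru_layout, iru_truth_table


@pytest.fixture(scope="session")
def bundle():
    """Packaged iru-like synthetic bundle at the fixed seed."""
    return iru_bundle(IRU_SEED)


@pytest.fixture(scope="session")
def truth_table():
    return iru_truth_table()


@pytest.fixture(scope="session")
def layout():
    return iru_layout()


@pytest.fixture(scope="session")
def result(bundle, layout):
    """Full pipeline output on the packaged fixture (path 1)."""
    return decode(bundle.proteins, layout, olefin_shift_path=1)


@pytest.fixture(scope="session")
def result_path2(bundle, layout):
    return decode(bundle.proteins, layout, olefin_shift_path=2)
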
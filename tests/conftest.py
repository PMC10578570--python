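import numpy as np
import pytest

from mcqkit import ResponseMatrix, load_packaged_bank


@pytest.fixture(scope="session")
def bank21():
    return load_packaged_bank(21)


@pytest.fixture(scope="session")
def bank27():
    return load_packaged_bank(27)


@pytest.fixture(params=[21, 27])
def bank(request, bank21, bank27):
    return bank21 if request.param == 21 else bank27


def make_matrix(values) -> ResponseMatrix:
    arr = np.asarray(values, dtype=float)
    return ResponseMatrix(
        ids=tuple(str(i + 1) for i in range(arr.shape[0])), values=arr
    )


@pytest.fixture()
def all_delayed_27(bank27):
    return make_matrix(np.ones((4, 27)))
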
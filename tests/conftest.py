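import numpy as np
import pytest

from fourmc import (
    Conv4mCClassifier,
    LabeledDataset,
    SequenceRecord,
    SyntheticSpec,
    encode_dataset,
    generate,
)


def random_sequence(rng: np.random.Generator, length: int = 41,
                    central_c: bool = True) -> str:
    chars = rng.choice(list("ACGTN"), size=length,
                       p=[0.2425, 0.2425, 0.2425, 0.2425, 0.03])
    if central_c:
        chars[(length - 1) // 2] = "C"
    return "".join(chars)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_ds():
    """10 hand-constructed records, balanced, valid 41-nt windows."""
    r = np.random.default_rng(7)
    records = [
        SequenceRecord(id=f"r{i}", seq=random_sequence(r), label=i % 2)
        for i in range(10)
    ]
    return LabeledDataset(records, name="tiny")


@pytest.fixture(scope="session")
def motif_ds():
    """Separable planted-motif dataset (CC at the center, p=1 vs q=0)."""
    return generate(SyntheticSpec(n_per_class=120, motif="CC",
                                  p_pos=1.0, p_neg=0.0, seed=11))


@pytest.fixture(scope="session")
def motif_model_be(motif_ds):
    """A CNN fitted on the binary encoding of the planted-motif data.

    Session-scoped: several interpretation tests probe the same model.
    """
    X, y = encode_dataset(motif_ds, "BE")
    est = Conv4mCClassifier(epochs=40, early_stopping_patience=40,
                            random_state=3)
    return est.fit(X, y)
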
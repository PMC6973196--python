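import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 genes with two classes."""
    from lgpsvm.data import ExpressionMatrix

    return ExpressionMatrix(
        values=np.array([[2.0, 1.0], [4.0, 5.0], [10.0, 3.0]]),
        sample_ids=["s1", "s2", "s3"],
        gene_ids=["gA", "gB"],
        labels=np.array([0, 0, 1]),
        class_names=["tumor", "normal"],
    )
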
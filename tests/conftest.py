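import numpy as np
import pytest

from bindsignal.network import ModelConfig, SignalModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Small but structurally complete model config (fast to run)."""
    return ModelConfig(
        conv_channels=(8, 12, 16),
        kernel_sizes=(7, 5, 3),
        pool_sizes=(5, 5, 5),
        gru_hidden=16,
        blend_channels=(12, 8, 8, 1),
        dropout_rate=0.2,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    model = SignalModel(tiny_config, seed=99)
    # randomize the (zero-initialized) output head so untrained-model
    # outputs depend on the input; several inference tests rely on that
    head = model.dec[3].conv.params["W"]
    head[...] = np.random.default_rng(7).normal(0, 0.2, head.shape).astype(np.float32)
    return model


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "toy.fa"
    path.write_text(">chrA\nACGTACGTacgt\nACGT\n>chrB\nGGGGCCCC\n")
    return path
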
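import numpy as np
import pytest

from agomet import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def assoc_dataset(tmp_path_factory):
    """Small planted-association dataset emitted to disk once per session."""
    outdir = tmp_path_factory.mktemp("assoc") / "ds"
    truth = synth.SyntheticTruth(seed=101, promoter_count=200)
    manifest = synth.emit_association_dataset(truth, outdir)
    return outdir, truth, manifest


@pytest.fixture(scope="session")
def clip_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("clip") / "ds"
    truth = synth.SyntheticTruth(seed=202, clip_n_reads=200)
    manifest = synth.emit_clip_dataset(truth, outdir)
    return outdir, truth, manifest
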
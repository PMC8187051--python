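import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mc4stack.sequence_io import SequenceWindow, WindowSet
from mc4stack.simulate import GeneratorConfig, generate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_window(seq: str, label=None, wid: str = "w") -> SequenceWindow:
    return SequenceWindow(id=wid, seq=seq, label=label)


@pytest.fixture
def window41() -> SequenceWindow:
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=41))
    seq = seq[:20] + "C" + seq[21:]
    return SequenceWindow(id="w41", seq=seq)


@pytest.fixture
def small_labelled_set() -> WindowSet:
    """60 + 60 mid-signal windows — enough for fast stacking smoke runs."""
    return generate(GeneratorConfig(n_pos=60, n_neg=60, seed=11))


@pytest.fixture
def tiny_fasta(tmp_path):
    """Write a 3-record 41-nt FASTA with central C and return its path."""
    rng = np.random.default_rng(5)
    records = []
    for i in range(3):
        seq = "".join(rng.choice(list("ACGT"), size=41))
        records.append((f"rec{i + 1}", seq[:20] + "C" + seq[21:]))
    path = tmp_path / "tiny.fasta"
    path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))
    return path, records
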
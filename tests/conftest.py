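from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PRIMER5 = "CCTACACGACGCTCTTCCGATCT"
PRIMER3 = "TCAGCCTCAACGGATACTCTCCC"


@pytest.fixture
def primers():
    return PRIMER5, PRIMER3


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def write_fastq(path: Path, reads: list[str], gz: bool = False) -> Path:
    text = "".join(
        f"@r{i}\n{read}\n+\n{'?' * len(read)}\n" for i, read in enumerate(reads)
    )
    if gz:
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)
    return path


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def mutate(seq: str, rng: np.random.Generator, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct positions."""
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        s[pos] = rng.permuted([b for b in "ACGT" if b != s[pos]])[0]
    return "".join(s)
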
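from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mitorecomb.genome import AnnotatedGenome, Feature
from mitorecomb.intervals import CircularInterval


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genome(seq: str, features=None, gid: str = "g") -> AnnotatedGenome:
    return AnnotatedGenome(id=gid, sequence=seq, features=features or [])


def iv(start: int, end: int, L: int) -> CircularInterval:
    return CircularInterval(start, end, L)


def gene(fid: str, start: int, end: int, L: int, strand="+", name=None, kind="gene"):
    return Feature(
        id=fid,
        kind=kind,
        interval=CircularInterval(start, end, L),
        strand=strand,
        gene_name=name if name is not None else fid,
    )
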
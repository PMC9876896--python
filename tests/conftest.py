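"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from archminer.hmmerio import DomainHit, quantize_evalue
from archminer.seqio import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_hit(
    target_id: str = "prot1",
    target_len: int = 1000,
    query_name: str = "DOM",
    env: tuple[int, int] = (1, 100),
    ali: tuple[int, int] | None = None,
    i_evalue: float = 1e-6,
    c_evalue: float | None = None,
    full_evalue: float | None = None,
    bitscore: float = 50.0,
    acc: float = 0.9,
    query_len: int | None = None,
) -> DomainHit:
    """A valid DomainHit with sensible defaults for targeted tests."""
    ali = ali or env
    L = ali[1] - ali[0] + 1
    return DomainHit(
        target_id=target_id,
        target_len=target_len,
        query_name=query_name,
        query_len=query_len or L,
        full_evalue=full_evalue if full_evalue is not None else i_evalue,
        bitscore=bitscore,
        c_evalue=c_evalue if c_evalue is not None else i_evalue,
        i_evalue=i_evalue,
        hmm_from=1,
        hmm_to=query_len or L,
        ali_from=ali[0],
        ali_to=ali[1],
        env_from=env[0],
        env_to=env[1],
        acc=acc,
    )


def random_hits(
    rng: np.random.Generator,
    n: int,
    target_id: str = "prot1",
    target_len: int = 500,
    quantized: bool = False,
) -> list[DomainHit]:
    """n random valid hits on one target (random envelopes and E-values)."""
    hits = []
    for k in range(n):
        start = int(rng.integers(1, target_len - 30))
        length = int(rng.integers(20, min(150, target_len - start + 1)))
        ev = float(10.0 ** rng.uniform(-12, -0.5))
        acc = float(rng.uniform(0.6, 1.0))
        bits = float(rng.uniform(5, 200))
        if quantized:
            ev, acc, bits = quantize_evalue(ev), round(acc, 2), round(bits, 1)
        hits.append(
            make_hit(
                target_id=target_id,
                target_len=target_len,
                query_name=f"D{k % 7}",
                env=(start, start + length - 1),
                i_evalue=ev,
                acc=acc,
                bitscore=bits,
            )
        )
    return hits


def random_records(rng: np.random.Generator, n: int) -> list[SequenceRecord]:
    out = []
    for k in range(n):
        length = int(rng.integers(1, 300))
        seq = "".join(rng.choice(list(AA), size=length))
        desc = "" if rng.random() < 0.3 else f"random protein {k}"
        out.append(SequenceRecord(f"rec{k}", desc, seq))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def example_rules_path(tmp_path):
    from importlib.resources import files

    p = tmp_path / "rules.yaml"
    p.write_text(files("archminer.data").joinpath("rules_example.yaml").read_text())
    return p
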
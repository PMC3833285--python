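import numpy as np
import pytest

from midsat.enzymes import IUPAC_SETS, load_enzyme_table
from midsat.genome_io import Genome
from midsat.pipeline import run_pipeline
from midsat.synth import make_paper_like_genome, random_background


@pytest.fixture(scope="session")
def panel():
    return load_enzyme_table()


@pytest.fixture(scope="session")
def paper_like():
    """The three-family synthetic fixture, generated once per session."""
    genome, truth = make_paper_like_genome(20130911)
    return genome, truth


@pytest.fixture(scope="session")
def paper_like_pipeline(paper_like, tmp_path_factory):
    """Full pipeline run on the fixture, plus its wall-clock runtime."""
    import time

    genome, _ = paper_like
    out = tmp_path_factory.mktemp("pipeline")
    t0 = time.perf_counter()
    result = run_pipeline(genome, ["HpaII", "RsaI", "FatI", "Kzo9I", "AluI"], out)
    elapsed = time.perf_counter() - t0
    return result, elapsed


@pytest.fixture()
def random_genome():
    def _make(seed: int, length: int = 10_000, gc: float = 0.5) -> Genome:
        g = Genome()
        g.add("rand", random_background(np.random.default_rng(seed), length, gc))
        return g

    return _make


def naive_site_scan(sequence: str, enzyme) -> list[int]:
    """Independent window-by-window IUPAC scan (vectorised truth-table lookup)."""
    rec = enzyme.recognition
    n, m = len(sequence), len(rec)
    if n < m:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    match = np.ones(n - m + 1, dtype=bool)
    for j, pat_char in enumerate(rec):
        allowed = np.zeros(256, dtype=bool)
        for b in IUPAC_SETS[pat_char]:  # genome N stays disallowed
            allowed[ord(b)] = True
        match &= allowed[arr[j : n - m + 1 + j]]
    return sorted({int(i) + enzyme.cut_offset for i in np.nonzero(match)[0]})
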
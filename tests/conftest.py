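import numpy as np
import pytest

from bidimr.harmonize import STATUS_ALIGNED, HarmonizedPair
from bidimr.sumstats import SnpRecord, SummaryStatsTable


def make_pairs(bx, by, sx=None, sy=None, prefix="rs"):
    """Build HarmonizedPair objects from effect arrays (defaults sx=sy=0.05)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sx = np.full_like(bx, 0.05) if sx is None else np.asarray(sx, dtype=float)
    sy = np.full_like(by, 0.05) if sy is None else np.asarray(sy, dtype=float)
    return [
        HarmonizedPair(f"{prefix}{i}", bx[i], sx[i], by[i], sy[i], STATUS_ALIGNED)
        for i in range(len(bx))
    ]


def random_pairs(rng, n, theta=0.2):
    """Random well-behaved harmonized pairs around a true ratio theta."""
    bx = rng.uniform(0.05, 0.5, n) * rng.choice([-1, 1], n)
    sx = rng.uniform(0.005, 0.05, n)
    sy = rng.uniform(0.005, 0.05, n)
    by = theta * bx + rng.normal(0, sy)
    return make_pairs(bx, by, sx, sy)


def make_record(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.02, pvalue=1e-9, **kw):
    return SnpRecord(rsid, ea, oa, beta, se, pvalue, **kw)


def make_table(records, trait_id="trait", source_id="study"):
    return SummaryStatsTable(trait_id=trait_id, source_id=source_id, records=tuple(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def regime_fixtures():
    """The bundled instrument-count-regime registry (built once per session)."""
    from bidimr.simulate import make_paper_regime_fixtures

    return make_paper_regime_fixtures(seed=7)
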
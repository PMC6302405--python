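import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from pairstitch.align import AlignParams, enumerate_offsets, score_overlap
from pairstitch.fastq import reverse_complement
from pairstitch.quality import QualityModel
from pairstitch.simulate import SimConfig, simulate


def brute_force_alignment(pair, params: AlignParams):
    """Independent exhaustive scorer: every offset, scalar scoring.

    Returns (offset, overlap_len, matches, mismatches, n_positions) for the
    minimum-mismatch-fraction valid placement (ties: larger overlap, then
    smaller |offset|), or None.
    """
    rc2 = reverse_complement(pair.r2.seq)
    best = None
    best_key = None
    for o in enumerate_offsets(len(pair.r1.seq), len(rc2), params):
        m, x, n, ol = score_overlap(pair.r1.seq, rc2, o)
        denom = m + x
        frac = x / denom if denom else 0.0
        if frac > params.max_mismatch_frac:
            continue
        key = (frac, -ol, abs(o))
        if best_key is None or key < best_key:
            best_key, best = key, (o, ol, m, x, n)
    return best


@pytest.fixture(scope="session")
def fastqjoin_model():
    return QualityModel.fastqjoin()


@pytest.fixture(scope="session")
def mixed_geometry_pairs():
    """300 simulated pairs spanning normal, contained, and dovetailed
    geometries, with occasional Ns."""
    cfg = SimConfig(
        n_pairs=300,
        seed=42,
        frag_mean=140.0,
        frag_sd=45.0,
        min_frag=50,
        max_frag=380,
        n_rate=0.003,
    )
    return list(simulate(cfg))


@pytest.fixture(scope="session")
def clean_pairs():
    """500 error-free pairs (quality high enough that no errors land)."""
    cfg = SimConfig(
        n_pairs=500,
        seed=7,
        quality=("constant", 41),
        frag_mean=160.0,
        frag_sd=25.0,
        min_frag=60,
        max_frag=180,
    )
    out = []
    for pair, truth in simulate(cfg):
        if not truth.r1_errors and not truth.r2_errors:
            out.append((pair, truth))
    return out


def rng(seed=0):
    return np.random.default_rng(seed)
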
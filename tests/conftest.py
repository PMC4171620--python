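import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import regenrich as rr
from regenrich.types import SnpRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study() -> rr.Study:
    """A small study with a planted effect, shared across read-only tests."""
    cfg = rr.SimulationConfig(
        n_cases=150, n_controls=150, n_blocks=20, snps_per_block=5,
        n_causal_blocks=4, seed=7,
    )
    return rr.simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study() -> rr.Study:
    """No planted association, no planted enrichment."""
    cfg = rr.SimulationConfig(
        n_cases=150, n_controls=150, n_blocks=20, snps_per_block=5,
        n_causal_blocks=0, causal_odds_ratio=1.0, enrichment_factor=1.0,
        seed=11,
    )
    return rr.simulate_study(cfg)


def make_panel(mafs, chrom="1", prefix="rs"):
    """Panel with given MAFs at 1 kb spacing."""
    return rr.SnpPanel(
        [
            SnpRecord(f"{prefix}{i}", chrom, 1 + 1000 * i, "A", "G", float(m))
            for i, m in enumerate(mafs)
        ]
    )


def bfs_component_count(snps, edges) -> int:
    """Independent connected-components oracle: adjacency sets + BFS."""
    adj = {s: set() for s in snps}
    for a, b in edges:
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    seen, n = set(), 0
    for s in snps:
        if s in seen:
            continue
        n += 1
        queue = [s]
        seen.add(s)
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
    return n


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
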
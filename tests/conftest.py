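import numpy as np
import pytest

from nbmature import LeadSpec, demo_lead
from nbmature.readproc import AA_ALPHABET
from nbmature.simulate import CampaignSimConfig
from nbmature.workflow import RunConfig, run_retrospective


@pytest.fixture(scope="session")
def lead20():
    """Small lead for unit tests: 20 residues, CDR-like mask."""
    return LeadSpec("MKTAYIAKQRQISFVKSHFS", frozenset({5, 6, 7, 12, 13}))


@pytest.fixture(scope="session")
def lead():
    return demo_lead()


def random_mutants(lead, n, rng, max_subs=3, positions=None):
    """Random multi-mutants of a lead (uniform positions/residues)."""
    pool = sorted(positions) if positions else list(range(1, len(lead) + 1))
    out = []
    for _ in range(n):
        k = rng.integers(1, max_subs + 1)
        chosen = rng.choice(pool, size=min(k, len(pool)), replace=False)
        chars = list(lead.sequence)
        for p in chosen:
            alts = [a for a in AA_ALPHABET if a != lead.sequence[p - 1]]
            chars[p - 1] = alts[rng.integers(len(alts))]
        out.append("".join(chars))
    return out


@pytest.fixture(scope="session")
def campaign():
    """Full-scale simulated campaign (seed 0) with trained models.

    Session-scoped because the retrospective run is the expensive shared
    substrate for the recovery, ranking and design-quality tests.
    """
    cfg = RunConfig(lead=demo_lead(), sim=CampaignSimConfig(seed=0), seed=0)
    retro = run_retrospective(cfg)
    return cfg, retro


@pytest.fixture(scope="session")
def small_campaign():
    """Desk-scale campaign for cheaper end-to-end checks."""
    sim = CampaignSimConfig(seed=3, library_size=4000, depth=25_000)
    cfg = RunConfig(lead=demo_lead(), sim=sim, seed=3)
    retro = run_retrospective(cfg)
    return cfg, retro
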
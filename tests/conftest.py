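"""Shared fixtures: simulated datasets and their code-comparison records.

The heavier simulations (parasite-like and host-like transcriptomes with
their per-code comparison records) are session-scoped so that every test
that needs them pays the alignment cost once.
"""

from __future__ import annotations

from dataclasses import replace

import pytest

import recodon as rc

PARASITE_SEED = 101
HOST_SEED = 102
TERMINAL_SEED = 103
UGA5_SEED = 104


@pytest.fixture(scope="session")
def tables() -> rc.CodeTableSet:
    return rc.load_tables()


@pytest.fixture(scope="session")
def parasite_sim():
    """Contingent-code transcriptome at the default study conditions."""
    cfg = rc.SimulationConfig(seed=PARASITE_SEED)
    proteome = rc.simulate_reference_proteome(cfg)
    transcripts, truth = rc.simulate_transcriptome(cfg, proteome)
    rc.audit_truth(transcripts, truth, cfg)
    return cfg, proteome, transcripts, truth


@pytest.fixture(scope="session")
def parasite_records(parasite_sim):
    cfg, proteome, transcripts, truth = parasite_sim
    db = rc.ReferenceDB(proteome)
    records = [rc.compare_codes(tid, seq, db) for tid, seq in transcripts.items()]
    return db, records


@pytest.fixture(scope="session")
def host_sim():
    """Standard-code (host-like) transcriptome, same divergence."""
    cfg = rc.SimulationConfig(seed=HOST_SEED).host_like()
    proteome = rc.simulate_reference_proteome(cfg)
    transcripts, truth = rc.simulate_transcriptome(cfg, proteome)
    rc.audit_truth(transcripts, truth, cfg)
    return cfg, proteome, transcripts, truth


@pytest.fixture(scope="session")
def host_records(host_sim):
    cfg, proteome, transcripts, truth = host_sim
    db = rc.ReferenceDB(proteome)
    records = [rc.compare_codes(tid, seq, db) for tid, seq in transcripts.items()]
    return db, records


@pytest.fixture(scope="session")
def terminal_sim():
    """Highly conserved complete transcripts for terminal-stop calling."""
    cfg = replace(rc.SimulationConfig(seed=TERMINAL_SEED),
                  divergence=0.05, n_transcripts=100)
    proteome = rc.simulate_reference_proteome(cfg)
    transcripts, truth = rc.simulate_transcriptome(cfg, proteome)
    db = rc.ReferenceDB(proteome)
    records = [rc.compare_codes(tid, seq, db) for tid, seq in transcripts.items()]
    return cfg, transcripts, truth, records


@pytest.fixture(scope="session")
def uga5_sim():
    """Coding UGA restricted to the 5' half of each protein."""
    cfg = replace(rc.SimulationConfig(seed=UGA5_SEED),
                  uga_5prime_half_only=True, n_transcripts=100)
    proteome = rc.simulate_reference_proteome(cfg)
    transcripts, truth = rc.simulate_transcriptome(cfg, proteome)
    db = rc.ReferenceDB(proteome)
    records = [rc.compare_codes(tid, seq, db) for tid, seq in transcripts.items()]
    return cfg, transcripts, truth, records
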
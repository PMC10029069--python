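"""Shared fixtures: toy transcripts and a session-wide curated scenario catalog."""

from __future__ import annotations

import pytest

from lofcurate.curation_engine import curate_cohort
from lofcurate.fixtures import CATALOG, generate_scenario, scenario_resources
from lofcurate.models import PROFILES, TranscriptModel


@pytest.fixture
def two_exon_plus() -> TranscriptModel:
    """Two coding exons, 1-based 101-200 and 301-400, plus strand (CDS 200)."""
    exons = [(100, 200), (300, 400)]
    return TranscriptModel("txp", "gA", "+", exons, list(exons))


@pytest.fixture
def two_exon_minus() -> TranscriptModel:
    """Same intervals on the minus strand: exon 0 is the rightmost."""
    exons = [(300, 400), (100, 200)]
    return TranscriptModel("txm", "gA", "-", exons, list(exons))


@pytest.fixture
def three_exon_plus() -> TranscriptModel:
    """Three coding exons of 120/81/99 bp (CDS 300), plus strand."""
    exons = [(50, 170), (260, 341), (431, 530)]
    return TranscriptModel("tx3", "gB", "+", exons, list(exons))


@pytest.fixture(scope="session")
def curated_catalog():
    """Every fixture scenario curated in memory under both profiles.

    Maps (scenario_name, profile_name) -> (scenario, CurationResult,
    PVS1Decision); computed once per session.
    """
    out = {}
    for name in sorted(CATALOG):
        scn = generate_scenario(name, seed=1)
        res = scenario_resources(scn)
        for prof_name, prof in PROFILES.items():
            results = curate_cohort(scn.bundles, res, prof)
            assert len(results) == 1
            out[(name, prof_name)] = (scn, results[0][0], results[0][1])
    return out
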
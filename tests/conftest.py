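"""Shared fixtures: a canonical synthetic transcriptome covering every
category and error type, plus its pipeline results (computed once)."""

from __future__ import annotations

import pytest

from domainfirst.pipeline import RunConfig, run_classic, run_novel
from domainfirst.synthfix import (
    Plant,
    PlantSpec,
    default_profiles,
    generate,
    plant_reference_panel,
)

CANONICAL_PLANTS = (
    Plant("SFK-like", frame=2),                                   # category 1
    Plant("PLCG-like", frame=1, error="split",
          split_after_domain=2, overlap=12),                      # category 2 x2
    Plant("BLNK-like", frame=-1, error="frameshift",
          split_after_domain=2),                                  # category 2
    Plant("ADAPTOR-like", frame=-2, error="novel"),               # category 3
    Plant("SFK-like", frame=3, error="duplicate"),                # 1 + duplicate
    Plant("ADAPTOR-like", frame=1, error="outside-orf"),          # excluded
    Plant("PLCG-like", frame=-3, error="truncate", keep_domains=3),  # category 2
)


@pytest.fixture(scope="session")
def panel():
    return plant_reference_panel()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def canonical_spec():
    return PlantSpec(n_background=12, seed=42, plants=CANONICAL_PLANTS)


@pytest.fixture(scope="session")
def canonical_truth(canonical_spec):
    return generate(canonical_spec)


@pytest.fixture(scope="session")
def novel_result(canonical_truth, panel, profiles):
    return run_novel(
        canonical_truth.transcripts, panel, RunConfig(seed=1), profiles=profiles
    )


@pytest.fixture(scope="session")
def classic_result(canonical_truth, panel, profiles):
    return run_classic(
        canonical_truth.transcripts, panel, RunConfig(), profiles=profiles
    )
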
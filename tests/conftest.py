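import dataclasses

import numpy as np
import pytest

from tfselect.pwm import PositionWeightMatrix
from tfselect.simulate import (PlantedMotif, SyntheticStudyConfig, demo_motifs,
                               simulate_study)
from tfselect.windows import CENTER, ContextClass, MutationRecord, MutationWindow


@pytest.fixture
def rng():
    return np.random.default_rng(20160623)


@pytest.fixture
def consensus_pwm():
    """Length-4 matrix whose consensus AAAA uniquely attains the maximal score."""
    return PositionWeightMatrix.from_counts("CONS4", [[100, 0, 0, 0]] * 4)


@pytest.fixture
def random_pwm(rng):
    return PositionWeightMatrix("RAND6", rng.normal(scale=1.5, size=(6, 4)))


def make_window(germline: str, alt: str, sample: str = "S0",
                chrom: str = "chr1", pos: int = 1000,
                cancer_type: str = "toy") -> MutationWindow:
    """Build a valid 101-nt window pair around index 50 from raw sequence."""
    assert len(germline) == 101
    ref = germline[CENTER]
    mutant = germline[:CENTER] + alt + germline[CENTER + 1:]
    mut = MutationRecord(chrom, pos, ref, alt, sample, cancer_type)
    ctx = ContextClass(germline[CENTER - 1], ref, alt, germline[CENTER + 1])
    return MutationWindow(mut, germline, mutant, ctx)


def random_window(rng, alt=None, **kwargs) -> MutationWindow:
    germ = "".join(rng.choice(list("ACGT"), size=101))
    ref = germ[CENTER]
    if alt is None:
        alt = rng.choice([b for b in "ACGT" if b != ref])
    return make_window(germ, alt, **kwargs)


def small_study_config(seed: int = 7, n_mutations: int = 1200,
                       genome_length: int = 600_000) -> SyntheticStudyConfig:
    """A fast planted study used by unit-level integration tests."""
    alpha, beta, _ = demo_motifs()
    return SyntheticStudyConfig(
        genome_length=genome_length,
        motifs=[PlantedMotif(alpha, density_per_kb=2.0),
                PlantedMotif(beta, density_per_kb=2.0, m_loss=0.7)],
        n_mutations=n_mutations, seed=seed)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_study_config())
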
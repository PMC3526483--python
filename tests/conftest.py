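"""Shared fixtures: small study designs and reusable fitted models."""

import numpy as np
import pytest

from modmind import (
    Dataset,
    GenConfig,
    McmcConfig,
    ModelSpec,
    StudyDesign,
    TaskDef,
    fit,
    generate,
    paper_design,
)


def make_design(species_counts: dict[str, int], task_rows) -> StudyDesign:
    """Small ad-hoc designs for fast tests.

    ``task_rows`` are (task_id, domain, response_type, n_trials) tuples.
    """
    subjects = tuple(
        (f"{sp}{i}", sp) for sp, n in species_counts.items() for i in range(1, n + 1)
    )
    tasks = tuple(TaskDef(*row) for row in task_rows)
    participation = frozenset(
        (sid, t.task_id) for sid, _ in subjects for t in tasks
    )
    return StudyDesign(
        species=tuple(species_counts),
        subjects=subjects,
        tasks=tasks,
        participation=participation,
    )


@pytest.fixture(scope="session")
def toy_design():
    """3 species x 2 subjects, 2 domains, one binomial and one rank task each."""
    return make_design(
        {"A": 2, "B": 2, "C": 2},
        [
            ("b1", "d1", "binomial", 4),
            ("r1", "d1", "rank", 1),
            ("b2", "d2", "binomial", 4),
            ("r2", "d2", "rank", 1),
        ],
    )


@pytest.fixture(scope="session")
def m3_dataset():
    """Paper-design dataset generated at the two-effect truth (0.17, 0.17, 0.66)."""
    cfg = GenConfig.from_proportions(
        paper_design(),
        {"species": 0.17, "species_domain": 0.17, "error": 0.66},
        seed=11,
    )
    dataset, truth = generate(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def m3_fit_small(m3_dataset):
    """A short M3 fit shared by assessment/summary tests (500 stored draws)."""
    dataset, _ = m3_dataset
    spec = ModelSpec.from_name("M3")
    return fit(dataset, spec, McmcConfig(n_burnin=500, n_iter=2_500, thin=5, seed=5))
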
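"""Shared fixtures: tiny hand-built cohorts and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from radefs.cohort import Cohort, ObservationMeta
from radefs.manifest import FeatureManifest


def make_manifest(names: list[str]) -> FeatureManifest:
    return FeatureManifest(tuple(names), {n: "firstorder" for n in names})


def make_cohort(
    X: np.ndarray,
    labels: list[str],
    node_ids: list[str] | None = None,
    feature_names: list[str] | None = None,
) -> Cohort:
    """One observation per row; node_ids default to one node per row."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    feature_names = feature_names or [f"firstorder_F{j}" for j in range(d)]
    node_ids = node_ids or [f"N{i:03d}" for i in range(n)]
    meta = [
        ObservationMeta(
            observation_id=f"obs{i}",
            node_id=node_ids[i],
            patient_id=f"P{i % 7}" if node_ids is None else f"P_{node_ids[i]}",
            phase="staging",
            label=labels[i],
        )
        for i in range(n)
    ]
    return Cohort(X, make_manifest(feature_names), meta)


def make_grouped_cohort(
    n_nodes: int,
    phases: int,
    d: int,
    labels_of_node,
    X_fn,
    seed: int = 0,
) -> Cohort:
    """Cohort with `phases` observations per node; X_fn(rng, n, d) builds X."""
    rng = np.random.default_rng(seed)
    n = n_nodes * phases
    X = X_fn(rng, n, d)
    phase_names = ["staging", "planning", "restaging"]
    meta = []
    for i in range(n_nodes):
        for ph in range(phases):
            meta.append(
                ObservationMeta(
                    observation_id=f"N{i:03d}_p{ph}",
                    node_id=f"N{i:03d}",
                    patient_id=f"P{i // 3:03d}",
                    phase=phase_names[ph % 3],
                    label=labels_of_node(i),
                )
            )
    manifest = make_manifest([f"firstorder_F{j}" for j in range(d)])
    return Cohort(X, manifest, meta)


@pytest.fixture(scope="session")
def default_cohort():
    from radefs.simulate import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def recovery_cohort():
    from radefs.simulate import generate_cohort, recovery_config

    return generate_cohort(recovery_config(seed=5))


@pytest.fixture(scope="session")
def sphere_fixture():
    from radefs.simulate import generate_toy_volume

    return generate_toy_volume(
        (32, 32, 32),
        {"kind": "sphere", "center": (16, 16, 16), "radii": 8, "intensity": 100},
        noise_sd=5.0,
        seed=3,
    )
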
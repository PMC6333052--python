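from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import HealthCheck, settings

from madsbox.align import ScoringScheme
from madsbox.classify import (
    CrossValidationResult,
    EvaluationReport,
    TrainedModel,
    cross_validate_recipes,
    evaluate,
    registered_recipes,
    train_all_models,
)
from madsbox.coils import CoilsConfig
from madsbox.features import EncoderConfigs, build_reference_databases
from madsbox.simdata import BenchmarkBundle, SyntheticFamilySpec, benchmark_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def coils_config() -> CoilsConfig:
    return CoilsConfig.default()


@pytest.fixture(scope="session")
def encoder_configs() -> EncoderConfigs:
    return EncoderConfigs()


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic family set for fast unit tests."""
    from madsbox.simdata import generate_families

    return generate_families(SyntheticFamilySpec(seed=7, n_per_class=3))


@dataclass
class Pipeline:
    """The full synthetic benchmark pipeline, built once per session."""

    bundle: BenchmarkBundle
    refdbs: dict
    models: list[TrainedModel]
    cv: dict[str, CrossValidationResult]
    heldout_report: EvaluationReport
    scheme: ScoringScheme
    configs: EncoderConfigs


@pytest.fixture(scope="session")
def pipeline(scheme, encoder_configs) -> Pipeline:
    """Generate the default benchmark, train all nine models, cross-validate
    them with per-fold reference rebuilds, and evaluate the held-out set."""
    bundle = benchmark_bundle(SyntheticFamilySpec(seed=BENCHMARK_SEED))
    refdbs = build_reference_databases(bundle.train)
    models = train_all_models(
        bundle.train, refdbs, scheme, encoder_configs, seed=BENCHMARK_SEED
    )
    cv = cross_validate_recipes(
        bundle.train, registered_recipes(), k=3, seed=BENCHMARK_SEED,
        scheme=scheme, configs=encoder_configs,
    )
    heldout = evaluate(bundle.test, models, refdbs, scheme, encoder_configs)
    return Pipeline(
        bundle=bundle,
        refdbs=refdbs,
        models=models,
        cv=cv,
        heldout_report=heldout,
        scheme=scheme,
        configs=encoder_configs,
    )
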
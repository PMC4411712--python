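"""Shared fixtures: small planted datasets reused across test modules."""

import pytest

from sistf.fixtures import (
    ExpressionSpec,
    SignatureSpec,
    generate_expression,
    generate_geneset,
    generate_metadata,
)


@pytest.fixture(scope="session")
def small_planted():
    """60 genes / 4 categories / 20 features; moderately noisy."""
    spec = SignatureSpec(
        n_genes_per_category=15,
        n_signature_features_per_category=2,
        n_noise_features=12,
        signature_presence_prob=0.85,
        leak_prob=0.15,
        seed=11,
    )
    geneset, truth, sig = generate_geneset(spec)
    return spec, geneset, truth, sig


@pytest.fixture(scope="session")
def separable_planted():
    """Zero-leak, full-presence planted set: perfectly separable."""
    spec = SignatureSpec(
        n_genes_per_category=10,
        n_signature_features_per_category=3,
        n_noise_features=4,
        signature_presence_prob=1.0,
        leak_prob=0.0,
        noise_presence_prob=0.0,
        seed=5,
    )
    geneset, truth, sig = generate_geneset(spec)
    return spec, geneset, truth, sig


@pytest.fixture(scope="session")
def headline_planted():
    """The planted-signature study design: 100 genes/category, 10+10+10+10
    signature features, 60 noise features, presence 0.9, leak 0.05."""
    spec = SignatureSpec(seed=7)
    geneset, truth, sig = generate_geneset(spec)
    return spec, geneset, truth, sig


@pytest.fixture(scope="session")
def labeled_metadata(small_planted):
    spec, geneset, truth, _ = small_planted
    metas, blast = generate_metadata(geneset, truth, seed=spec.seed)
    return geneset, truth, metas, blast


@pytest.fixture(scope="session")
def noiseless_expression():
    spec = ExpressionSpec(n_genes=500, planted_mf_fraction=0.1, mf_fold=4.0,
                          noise_sd=0.0, seed=3)
    matrix, planted = generate_expression(spec)
    return spec, matrix, planted
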
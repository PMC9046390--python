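"""Shared session fixtures: generated toy datasets and derived matrices.

Everything is generated at test time from seeded generators; nothing is
read from checked-in data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from utr3pred.coverage import read_coverage
from utr3pred.features import extract_feature_matrix, load_conversion_tables
from utr3pred.fixtures import CLASS_LABELS, FixtureSpec, generate_training_fixture
from utr3pred.genome import open_genome
from utr3pred.regions import GenomicRegion, read_regions


@pytest.fixture(scope="session")
def training_fixture(tmp_path_factory):
    """Default strong-contrast corpus: 50 per class, 2 tissues, 20+20 ERs."""
    spec = FixtureSpec(seed=11, n_er_true=20, n_er_noise=20)
    return generate_training_fixture(spec, tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def loaded_resources(training_fixture):
    fx = training_fixture
    return {
        "genome": open_genome(fx.genome),
        "tracks": [read_coverage(path, tissue) for tissue, path in sorted(fx.coverage.items())],
        "conservation": read_coverage(fx.conservation, "conservation"),
        "repeats": read_regions(fx.repeats),
        "tables": load_conversion_tables(fx.structural_tables),
    }


def truth_regions(truth: pd.DataFrame) -> list[GenomicRegion]:
    return [
        GenomicRegion(r.chrom, r.start, r.end, r.strand, r.element_id)
        for r in truth.itertuples()
    ]


@pytest.fixture(scope="session")
def feature_matrix(training_fixture, loaded_resources):
    fx = training_fixture
    res = loaded_resources
    matrix = extract_feature_matrix(
        truth_regions(fx.truth),
        res["genome"],
        res["tracks"],
        conservation=res["conservation"],
        repeats=res["repeats"],
        tables=res["tables"],
    )
    labels = fx.truth["label"].to_numpy()
    return matrix, labels


@pytest.fixture(scope="session")
def binary_labels(feature_matrix):
    _, labels = feature_matrix
    return np.where(labels == "THREE_UTR", "THREE_UTR", "NON_UTR3")


@pytest.fixture(scope="session")
def acceptance_corpus(tmp_path_factory):
    """n = 600 corpus (100 per class) used by the classifier sanity checks."""
    spec = FixtureSpec(
        seed=29,
        class_counts={label: 100 for label in CLASS_LABELS},
        n_er_true=25,
        n_er_noise=25,
    )
    fx = generate_training_fixture(spec, tmp_path_factory.mktemp("corpus600"))
    genome = open_genome(fx.genome)
    tracks = [read_coverage(path, tissue) for tissue, path in sorted(fx.coverage.items())]
    conservation = read_coverage(fx.conservation, "conservation")
    repeats = read_regions(fx.repeats)
    tables = load_conversion_tables(fx.structural_tables)
    matrix = extract_feature_matrix(
        truth_regions(fx.truth), genome, tracks,
        conservation=conservation, repeats=repeats, tables=tables,
    )
    labels = fx.truth["label"].to_numpy()
    resources = {
        "genome": genome,
        "tracks": tracks,
        "conservation": conservation,
        "repeats": repeats,
        "tables": tables,
    }
    return fx, matrix, labels, resources
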
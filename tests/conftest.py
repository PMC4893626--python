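import numpy as np
import pandas as pd
import pytest

from hebkit.de_stats import CountMatrix
from hebkit.synthetic_data import (
    SimDesign,
    generate_counts,
    generate_genomes,
    generate_homoeolog_counts,
)


@pytest.fixture(scope="session")
def small_design() -> SimDesign:
    """A light but fully featured experiment: 300 genes, 200k reads/library.

    The baseline-expression spread is tightened relative to the default:
    with only 300 genes a heavy lognormal tail lets a single transcript
    dominate a library total, which shifts every gene's relative
    expression (composition bias) — real at this scale, but noise for
    unit-level checks of the classifiers.
    """
    return SimDesign(n_genes=300, depth=2e5, weight_sigma=0.6, seed=101)


@pytest.fixture(scope="session")
def small_sim(small_design):
    genomes = generate_genomes(small_design)
    bundle = generate_counts(small_design, genomes)
    homoeolog = generate_homoeolog_counts(small_design, genomes, bundle)
    return small_design, genomes, bundle, homoeolog


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_design):
    """The small simulation written out as a file bundle."""
    from hebkit.synthetic_data import write_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    write_bundle(small_design, outdir)
    return outdir


def toy_count_matrix(counts: dict, lengths=None, lib_sizes=None, groups=None):
    """Hand-rolled CountMatrix for arithmetic-level tests."""
    df = pd.DataFrame(counts)
    if lengths is None:
        lengths = pd.Series(1000.0, index=df.index)
    if lib_sizes is None:
        lib_sizes = pd.Series(1e6, index=df.columns)
    if groups is None:
        groups = pd.Series({c: c.rsplit("_", 1)[0] for c in df.columns})
    return CountMatrix(df, pd.Series(lengths, index=df.index), lib_sizes, groups)
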
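import pytest

from karyodrive import datasets
from karyodrive.phylo import build_pairs, find_system_clusters, read_tree


@pytest.fixture(scope="session")
def reference_records():
    return datasets.load_reference_table()


@pytest.fixture(scope="session")
def reference_recmap(reference_records):
    return {r.key: r for r in reference_records}


@pytest.fixture(scope="session")
def reference_tree(reference_records):
    return read_tree(datasets.load_reference_tree_text(),
                     [r.key for r in reference_records])


@pytest.fixture(scope="session")
def reference_units(reference_tree, reference_records):
    return find_system_clusters(
        reference_tree,
        {r.key: r.system for r in reference_records},
        {r.key: r.genus for r in reference_records},
    )


@pytest.fixture(scope="session")
def reference_pairs(reference_tree, reference_units):
    return build_pairs(reference_tree, reference_units, datasets.load_reference_pairs())
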
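import random

import pytest

from enamelevo.timetree import TimeTree


def make_random_timetree(rnd: random.Random, n_tips: int) -> TimeTree:
    """Random coalescent-style rooted timetree with unit age steps."""
    nodes = [(f"t{i}", 0.0) for i in range(n_tips)]
    age = 0.0
    while len(nodes) > 1:
        age += 1.0
        i, j = sorted(rnd.sample(range(len(nodes)), 2))
        (si, ai), (sj, aj) = nodes[i], nodes[j]
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append((f"({si}:{age - ai},{sj}:{age - aj})", age))
    return TimeTree.from_newick(nodes[0][0] + ";")


def record_key(rec):
    """Identity of a lesion event for multiset comparisons."""
    return (rec.gene, rec.kind.name, rec.exon_start, rec.exon_end,
            rec.intron, rec.start, rec.end, rec.bases, tuple(rec.taxa))


@pytest.fixture
def rnd():
    return random.Random(20240228)


@pytest.fixture(scope="session")
def species_tree_93():
    from enamelevo import io as eio
    return eio.load_species_tree(93)


@pytest.fixture(scope="session")
def lesion_catalog():
    from enamelevo import io as eio
    return eio.load_lesion_catalog()


@pytest.fixture(scope="session")
def taxon_table():
    from enamelevo import io as eio
    return eio.load_taxon_table()
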
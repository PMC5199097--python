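import numpy as np
import pytest

from aylacostoma import (
    PaperFixtureSpec,
    build_paper_alignment,
    distance_matrix,
    paper_groups,
)


@pytest.fixture(scope="session")
def paper_alignment():
    return build_paper_alignment(PaperFixtureSpec(seed=0))


@pytest.fixture(scope="session")
def species_groups():
    return paper_groups()


@pytest.fixture(scope="session")
def species_reps(species_groups):
    """One representative sequence ID per species (single haplotype each)."""
    return {sp: ids[0] for sp, ids in species_groups.items()}


@pytest.fixture(scope="session")
def paper_dm_k2p(paper_alignment):
    return distance_matrix(paper_alignment, model="k2p", deletion="pairwise")


def random_additive_tree(rng: np.random.Generator, n_leaves: int) -> str:
    """Random binary topology with uniform(0.05, 1) branch lengths, as Newick.

    Used as an oracle: the patristic matrix of this tree is additive, so
    neighbour joining must recover topology and path lengths exactly.
    """
    items = [f"L{i}" for i in range(n_leaves)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(int(j))
        a = items.pop(int(i))
        la, lb = rng.uniform(0.05, 1.0, size=2)
        items.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return items[0] + ";"
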
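import pytest

from pcgkit import AbundanceTable, Phylogeny


@pytest.fixture
def balanced_tree() -> Phylogeny:
    """((A:1,B:1):1,(C:1,D:1):1); — two cherries, root height 2."""
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def worked_table() -> AbundanceTable:
    """Three samples over A..D where no single taxon is ubiquitous but both
    cherries are: s1 {A=5,C=2}, s2 {B=3,C=1}, s3 {A=2,D=4}."""
    return AbundanceTable(
        [[5, 0, 2, 0], [0, 3, 1, 0], [2, 0, 0, 4]],
        ["s1", "s2", "s3"],
        ["A", "B", "C", "D"],
    )
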
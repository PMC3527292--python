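import numpy as np
import pytest

from napmut.ancestral_changes import Phylogeny, TreeNode


def build_tree(spec, outgroup="OUT"):
    """Tiny helper: build a tree from a nested spec of
    (name, length, support, children)."""

    def make(node_spec):
        name, length, support, children = node_spec
        node = TreeNode(name=name, length=length, support=support)
        for c in children:
            node.add_child(make(c))
        return node

    return Phylogeny(make(spec), outgroup=outgroup)


@pytest.fixture
def quartet_tree():
    """((A,B),(C,D)) plus an outgroup, all supports high."""
    spec = (
        None, 0.0, 100.0,
        [
            (
                None, 0.05, 99.0,
                [
                    ("AB", 0.05, 99.0, [("A", 0.05, None, []), ("B", 0.05, None, [])]),
                    ("CD", 0.05, 99.0, [("C", 0.05, None, []), ("D", 0.05, None, [])]),
                ],
            ),
            ("OUT", 0.15, None, []),
        ],
    )
    return build_tree(spec)


def sites_from_columns(columns, strain_order, positions=None):
    """Build an AnalyzableSites from explicit polymorphic columns
    ({strain: base} dicts)."""
    import pandas as pd

    from napmut.ancestral_changes import BASE_CODE, AnalyzableSites

    states = np.array(
        [[BASE_CODE[col[s]] for s in strain_order] for col in columns], dtype=np.int8
    )
    if positions is None:
        positions = np.arange(len(columns))
    census = pd.DataFrame(
        {
            "position": positions,
            "ref_base": [col[strain_order[0]] for col in columns],
            "polymorphic": True,
        }
    )
    return AnalyzableSites(census=census, states=states, strain_order=list(strain_order))
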
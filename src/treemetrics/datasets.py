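"""Bundled example data."""

from __future__ import annotations

from importlib import resources

from .io import read_phylip_dm
from .matrix import DistanceMatrix


def worked_example() -> DistanceMatrix:
    """The 4-taxon distance matrix (taxa u, v, x, y) used throughout the
    documentation: a metric whose quartet signal points to the wrong tree
    until the saturating distortion ``d = 1 - exp(-t/10)`` is undone.
    Entries are printed to three decimals.
    """
    with resources.as_file(
        resources.files("treemetrics").joinpath("data/worked_example.phy")
    ) as p:
        return read_phylip_dm(p, tol=1e-6)
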
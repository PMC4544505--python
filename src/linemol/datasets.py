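"""Packaged example molecules shipped as plain edge lists."""

from __future__ import annotations

from importlib.resources import files

from .graph_core import MolecularGraph, read_graph

__all__ = ["EXAMPLES", "example_text", "load_example"]

#: Names of the packaged examples: a 4-bead lumped model of
#: methylcyclopropane and the 12-bead coarse-grained taurocholate bile salt
#: model of Vila Verde and Frenkel.
EXAMPLES = ("methylcyclopropane", "taurocholate")


def example_text(name: str) -> str:
    """Raw edge-list text of a packaged example."""
    if name not in EXAMPLES:
        raise KeyError(f"unknown example {name!r}; available: {EXAMPLES}")
    return (files("linemol") / "data" / f"{name}.edges").read_text()


def load_example(name: str) -> MolecularGraph:
    """Parse a packaged example into a :class:`MolecularGraph`."""
    return read_graph(example_text(name))
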
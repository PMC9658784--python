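"""Graph persistence: JSON node-link structure plus an array archive.

The JSON document carries the topology (node names, type tags, per-node
configuration, edges with keys and receptor restrictions) and stays
human-diffable; numeric parameter blobs (kernels, weight vectors) are
referenced by ``<node>/<name>`` into a sibling compressed ``.npz`` archive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .graph import ComputationGraph
from .layers import NODE_TYPES

__all__ = ["graph_to_node_link", "graph_from_node_link",
           "save_graph", "load_graph"]


def graph_to_node_link(g: ComputationGraph) -> tuple[dict, dict]:
    """Serialise a graph to (node-link dict, named array blobs)."""
    nodes = []
    arrays: dict[str, np.ndarray] = {}
    for rec in g.records():
        cls = type(rec.node)
        if cls.__name__ not in NODE_TYPES:
            raise TypeError(
                f"node type {cls.__name__} is not registered for "
                "serialisation")
        config, blobs = rec.node.get_config()
        nodes.append({"id": rec.name, "type": cls.__name__,
                      "config": config})
        for name, arr in blobs.items():
            arrays[f"{rec.name}/{name}"] = np.asarray(arr)
    links = [{"source": e.src, "target": e.dst, "key": e.key,
              "receptors": list(e.receptors)} for e in g.edges()]
    data = {"directed": True, "multigraph": True,
            "nodes": nodes, "links": links, "meta": {}}
    return data, arrays


def graph_from_node_link(data: dict, arrays: dict | None = None
                         ) -> ComputationGraph:
    arrays = arrays or {}
    g = ComputationGraph()
    for entry in data["nodes"]:
        cls = NODE_TYPES.get(entry["type"])
        if cls is None:
            raise TypeError(f"unknown node type {entry['type']!r}")
        prefix = f"{entry['id']}/"
        blobs = {k[len(prefix):]: v for k, v in arrays.items()
                 if k.startswith(prefix)}
        g.add_node(entry["id"],
                   cls.from_config(entry.get("config", {}), blobs))
    for link in data["links"]:
        g.add_edge(link["source"], link["target"], key=link.get("key"),
                   receptors=tuple(link.get("receptors",
                                            ("forward", "backward"))))
    return g


def save_graph(g: ComputationGraph, path) -> Path:
    """Write ``path`` (JSON) and, when parameters exist, ``path`` + .npz."""
    path = Path(path)
    data, arrays = graph_to_node_link(g)
    if arrays:
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        data["meta"]["arrays"] = path.with_suffix(".npz").name
    path.write_text(json.dumps(data, indent=2, sort_keys=True))
    return path


def load_graph(path) -> ComputationGraph:
    path = Path(path)
    data = json.loads(path.read_text())
    arrays = {}
    archive = data.get("meta", {}).get("arrays")
    if archive:
        with np.load(path.parent / archive) as npz:
            arrays = {k: npz[k] for k in npz.files}
    return graph_from_node_link(data, arrays)
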
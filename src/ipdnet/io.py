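"""Serialization glue: edge-list graph I/O, test fixtures, run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .netgen import Network, generate_ba

__all__ = ["read_edge_list", "write_edge_list", "make_fixture", "RunManifest"]


def read_edge_list(path) -> Network:
    """Read a two-column whitespace edge list (0-based ids, one undirected
    edge per line). Self-loops and duplicate edges are rejected."""
    edges = []
    max_node = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if len(parts) != 2:
                    raise ValueError
                u, v = int(parts[0]), int(parts[1])
                if u < 0 or v < 0:
                    raise ValueError
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}") from None
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u}-{v}")
            edges.append((u, v))
            max_node = max(max_node, u, v)
    net = Network(n=max_node + 1, edges=np.array(edges, dtype=np.int64).reshape(-1, 2))
    return net


def write_edge_list(net: Network, path) -> None:
    """Write the canonical edge list (lower id first, sorted rows)."""
    with open(path, "w") as fh:
        for u, v in net.edges:
            fh.write(f"{u} {v}\n")


def make_fixture(name: str) -> Network:
    """Small deterministic graphs for unit tests.

    ring4: 4-cycle, degrees (2,2,2,2). star5: hub 0 with 4 leaves.
    two_triangles: triangles 0-1-2 and 3-4-5 bridged by edge 2-3.
    tiny_ba: BA growth (N=8, m=m0=3) from a fixed seed, 18 edges.
    """
    if name == "ring4":
        edges = [(0, 1), (1, 2), (2, 3), (0, 3)]
        return Network(4, np.array(edges))
    if name == "star5":
        return Network(5, np.array([(0, i) for i in range(1, 5)]))
    if name == "two_triangles":
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
        return Network(6, np.array(edges))
    if name == "tiny_ba":
        return generate_ba(8, 3, 3, rng=12345)
    raise ValueError(f"unknown fixture {name!r}")


@dataclass
class RunManifest:
    """Reproducibility record for a sweep: the root seed, a hash of the
    plan, and the substream ids actually used."""

    tool_version: str
    root_seed: int
    plan_hash: str
    substreams: list[tuple[int, int, int]] = field(default_factory=list)
    timestamp: float = field(default_factory=time.time)

    @staticmethod
    def hash_plan(plan) -> str:
        payload = {
            "network": plan.network,
            "measure": plan.measure,
            "matches": [(w.token, s.token) for w, s in plan.matches],
            "alphas": [float(a) for a in plan.alphas],
            "replicates": plan.replicates,
            "epoch_rounds": plan.config.epoch_rounds,
            "max_rounds": plan.config.max_rounds,
            "tail_rounds": plan.config.tail_rounds,
            "reset_each_epoch": plan.config.reset_each_epoch,
            "fresh_network_per_replicate": plan.fresh_network_per_replicate,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_json(self) -> str:
        d = asdict(self)
        d["substreams"] = [list(s) for s in self.substreams]
        return json.dumps(d, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        d["substreams"] = [tuple(s) for s in d["substreams"]]
        return cls(**d)
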
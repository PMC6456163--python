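"""Ontogenetic branch topology of a sampled plant.

A plant individual is represented as a rooted tree of branch nodes. Each
node corresponds to a developmental unit (a trunk, a primary branch, a
sub-branch, a runner segment, a root branch, ...) formed in a particular
growing season. Sequenced samples (leaves, roots, petals, runner pieces,
...) attach to nodes and carry tissue and sequencing-lane metadata.

The central operation is the focal/control partition for a node: the focal
set is every sample placed at the node or any of its descendants, the
control set is every other sample of the same individual. Somatic mutation
calling compares focal against control sample groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

TISSUES = frozenset(
    {
        "leaf",
        "root",
        "petal",
        "glume",
        "lemma",
        "runner",
        "stem",
        "bark",
        "seed",
        "tiller",
        "callus",
    }
)


class TopologyError(ValueError):
    """Raised when a topology file or object violates a structural invariant."""


@dataclass(frozen=True)
class SampleRecord:
    """A sequenced sample attached to a branch node."""

    sample_id: str
    node_id: str
    tissue: str
    lane_id: str | None = None
    individual_id: str = ""

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise TopologyError(
                f"sample {self.sample_id!r}: unknown tissue {self.tissue!r} "
                f"(expected one of {sorted(TISSUES)})"
            )


@dataclass(frozen=True)
class BranchNode:
    """A branch (developmental unit) of the plant.

    ``year_formed`` is a season index counted from the root (root = 0);
    ``age_years`` is the elapsed age of the branch at sampling time and is
    optional (rate computations require it and reject topologies without it).
    """

    node_id: str
    parent_id: str | None = None
    year_formed: int = 0
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise TopologyError(f"node {self.node_id!r}: negative age_years")


@dataclass(frozen=True)
class BranchPartition:
    """Focal (within-branch) versus control (rest-of-plant) sample sets."""

    focal: frozenset[str]
    control: frozenset[str]


class PlantTopology:
    """Validated branch hierarchy plus sample placement for one individual.

    Parameters
    ----------
    individual_id:
        Identifier of the plant. Grafted individuals whose shoot and root
        systems are analysed separately share an ``individual_id`` prefix and
        differ in ``subsystem``.
    genome_size:
        Reference genome size in bp.
    ploidy:
        Genome copy number per cell (2 for the diploids analysed here).
    nodes, samples:
        Branch nodes and sample records. Exactly one node must be the root
        (``parent_id is None``), ids must be unique, parent links acyclic and
        every sample must reference an existing node.
    age_years:
        Optional individual-level age; per-node ``age_years`` wins when both
        are present.
    """

    def __init__(
        self,
        individual_id: str,
        genome_size: int,
        nodes: list[BranchNode],
        samples: list[SampleRecord],
        ploidy: int = 2,
        age_years: float | None = None,
        subsystem: str | None = None,
    ) -> None:
        self.individual_id = individual_id
        self.genome_size = int(genome_size)
        self.ploidy = int(ploidy)
        self.nodes = list(nodes)
        self.samples = list(samples)
        self.age_years = age_years
        self.subsystem = subsystem
        self._node_by_id: dict[str, BranchNode] = {}
        self._children: dict[str, list[str]] = {}
        self._samples_by_node: dict[str, list[SampleRecord]] = {}
        self._sample_by_id: dict[str, SampleRecord] = {}
        self._root: str | None = None
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if self.genome_size <= 0:
            raise TopologyError("genome_size must be positive")
        if self.ploidy <= 0:
            raise TopologyError("ploidy must be positive")
        roots = []
        for node in self.nodes:
            if node.node_id in self._node_by_id:
                raise TopologyError(f"duplicate node id {node.node_id!r}")
            self._node_by_id[node.node_id] = node
            self._children.setdefault(node.node_id, [])
            if node.parent_id is None:
                roots.append(node.node_id)
        if len(roots) != 1:
            raise TopologyError(
                f"expected exactly one root node, found {len(roots)}: {roots}"
            )
        self._root = roots[0]
        for node in self.nodes:
            if node.parent_id is not None:
                if node.parent_id not in self._node_by_id:
                    raise TopologyError(
                        f"node {node.node_id!r} references missing parent "
                        f"{node.parent_id!r}"
                    )
                self._children[node.parent_id].append(node.node_id)
        # acyclicity: walk each node to the root, bounded by node count
        for node in self.nodes:
            seen = set()
            cur: str | None = node.node_id
            while cur is not None:
                if cur in seen:
                    raise TopologyError(f"cycle in parent links at node {cur!r}")
                seen.add(cur)
                cur = self._node_by_id[cur].parent_id
        for sample in self.samples:
            if sample.sample_id in self._sample_by_id:
                raise TopologyError(f"duplicate sample id {sample.sample_id!r}")
            if sample.node_id not in self._node_by_id:
                raise TopologyError(
                    f"sample {sample.sample_id!r} references missing node "
                    f"{sample.node_id!r}"
                )
            self._sample_by_id[sample.sample_id] = sample
            self._samples_by_node.setdefault(sample.node_id, []).append(sample)

    # -- basic accessors ----------------------------------------------------

    @property
    def root(self) -> str:
        assert self._root is not None
        return self._root

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def node(self, node_id: str) -> BranchNode:
        try:
            return self._node_by_id[node_id]
        except KeyError:
            raise TopologyError(f"unknown node id {node_id!r}") from None

    def sample(self, sample_id: str) -> SampleRecord:
        try:
            return self._sample_by_id[sample_id]
        except KeyError:
            raise TopologyError(f"unknown sample id {sample_id!r}") from None

    def children(self, node_id: str) -> list[str]:
        self.node(node_id)
        return list(self._children.get(node_id, []))

    def descendants(self, node_id: str) -> list[str]:
        """Node ids of the subtree rooted at ``node_id`` (inclusive), preorder."""
        self.node(node_id)
        out, stack = [], [node_id]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(reversed(self._children.get(cur, [])))
        return out

    def samples_at(self, node_id: str) -> list[SampleRecord]:
        """Samples placed directly at ``node_id``."""
        self.node(node_id)
        return list(self._samples_by_node.get(node_id, []))

    def focal_samples(self, node_id: str) -> frozenset[str]:
        """Sample ids at ``node_id`` and every descendant node."""
        out: set[str] = set()
        for nid in self.descendants(node_id):
            out.update(s.sample_id for s in self._samples_by_node.get(nid, []))
        return frozenset(out)

    def node_age(self, node_id: str) -> float | None:
        """Age of a node in years; per-node value wins over the individual age."""
        node = self.node(node_id)
        if node.age_years is not None:
            return node.age_years
        if self.age_years is not None:
            # individual-level age minus the seasons elapsed before the node formed
            return max(self.age_years - node.year_formed, 0.0)
        return None

    def path_to_root(self, node_id: str) -> list[str]:
        out = []
        cur: str | None = node_id
        while cur is not None:
            out.append(cur)
            cur = self.node(cur).parent_id
        return out

    def primary_branch(self, node_id: str) -> str:
        """The child-of-root ancestor of ``node_id`` (the node itself if root)."""
        path = self.path_to_root(node_id)
        return path[-2] if len(path) >= 2 else path[-1]

    def lca(self, sample_ids) -> str:
        """Lowest common ancestor node of a nonempty set of samples."""
        sample_ids = list(sample_ids)
        if not sample_ids:
            raise TopologyError("lca of empty sample set")
        paths = [self.path_to_root(self.sample(s).node_id) for s in sample_ids]
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common node appears first on any path
        for nid in paths[0]:
            if nid in common:
                return nid
        raise TopologyError("disconnected topology")  # pragma: no cover

    # -- export -------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string of the branch-node hierarchy (nodes only, unit lengths)."""

        def fmt(nid: str) -> str:
            kids = self._children.get(nid, [])
            if not kids:
                return nid
            return "(" + ",".join(fmt(k) for k in kids) + ")" + nid

        return fmt(self.root) + ";"

    def to_dict(self) -> dict:
        d: dict = {
            "individual_id": self.individual_id,
            "genome_size": self.genome_size,
            "ploidy": self.ploidy,
            "nodes": [
                {
                    "id": n.node_id,
                    "parent": n.parent_id,
                    "year_formed": n.year_formed,
                    **({"age_years": n.age_years} if n.age_years is not None else {}),
                }
                for n in self.nodes
            ],
            "samples": [
                {
                    "id": s.sample_id,
                    "node": s.node_id,
                    "tissue": s.tissue,
                    **({"lane": s.lane_id} if s.lane_id is not None else {}),
                }
                for s in self.samples
            ],
        }
        if self.age_years is not None:
            d["age_years"] = self.age_years
        if self.subsystem is not None:
            d["subsystem"] = self.subsystem
        return d


def load_topology(path) -> PlantTopology:
    """Load and validate a plant topology from a YAML file.

    Schema (see also :meth:`PlantTopology.to_dict`)::

        individual_id: GL2
        genome_size: 225000000
        ploidy: 2            # optional, default 2
        age_years: 420       # optional individual-level age
        subsystem: shoot     # optional tag for grafted individuals
        nodes:
          - {id: root, parent: null, year_formed: 0}
          - {id: B1, parent: root, year_formed: 1, age_years: 5}
        samples:
          - {id: B1-L1, node: B1, tissue: leaf, lane: L001}
    """
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise TopologyError(f"cannot parse topology file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise TopologyError(f"topology file {path} is not a mapping")
    return topology_from_dict(doc)


def topology_from_dict(doc: dict) -> PlantTopology:
    for key in ("individual_id", "genome_size", "nodes", "samples"):
        if key not in doc:
            raise TopologyError(f"topology document missing required key {key!r}")
    individual = str(doc["individual_id"])
    nodes = [
        BranchNode(
            node_id=str(n["id"]),
            parent_id=None if n.get("parent") is None else str(n["parent"]),
            year_formed=int(n.get("year_formed", 0)),
            age_years=n.get("age_years"),
        )
        for n in doc["nodes"]
    ]
    samples = [
        SampleRecord(
            sample_id=str(s["id"]),
            node_id=str(s["node"]),
            tissue=str(s["tissue"]),
            lane_id=None if s.get("lane") is None else str(s["lane"]),
            individual_id=individual,
        )
        for s in doc["samples"]
    ]
    return PlantTopology(
        individual_id=individual,
        genome_size=int(doc["genome_size"]),
        ploidy=int(doc.get("ploidy", 2)),
        nodes=nodes,
        samples=samples,
        age_years=doc.get("age_years"),
        subsystem=doc.get("subsystem"),
    )


def save_topology(topology: PlantTopology, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(topology.to_dict(), fh, sort_keys=False)


def branch_partition(topology: PlantTopology, node_id: str) -> BranchPartition:
    """Focal = samples of ``node_id`` and its descendants; control = the rest."""
    focal = topology.focal_samples(node_id)
    control = frozenset(topology.sample_ids) - focal
    return BranchPartition(focal=focal, control=control)
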
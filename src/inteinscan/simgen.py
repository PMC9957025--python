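"""Synthetic protein families carrying mobile insertion elements.

The generator emulates the situation observed in phage DNA-methylase
families: a divergent host-protein family (the "extein") in which up to
three insertion elements (an intein, a second homing endonuclease, an
uncharacterised domain) sit at fixed positions, each present in only a
patchy subset of carriers.  Element histories combine

* vertical descent from one or more origin points on the host tree,
* horizontal transfer between contemporaneous lineages (a Poisson process),
* homing sweeps: the element of one donor is copied *verbatim* into a group
  of already-diverged hosts, producing identical element sequences inside
  divergent exteins — the signature of a recent local invasion.

Everything is seeded and returns full ground truth (host tree, per-element
genealogies, site sets, carrier sets, event log) so downstream detection,
partitioning, tree inference and transfer tests can be validated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .alnio import Alignment, write_fasta
from .phylocore.models import AA_ORDER, SubstModel, parse_model_spec


# --------------------------------------------------------------------- types
@dataclass
class ElementSpec:
    """One insertion element: geometry, origin count and transfer process."""

    name: str
    length: int
    insertion_column: int          # 0-based extein residue index
    n_origins: int = 1
    hgt_rate: float = 0.0          # events per carrier lineage per unit time
    homing_groups: list[list[str]] = field(default_factory=list)
    element_model_scale: float = 1.0
    min_carriers: int = 2          # redraw histories outside these carrier
    max_carrier_fraction: float = 1.0   # bounds (patchiness conditioning)

    def validate(self, extein_length: int) -> None:
        if self.length < 1:
            raise ValueError(f"element {self.name!r}: length must be >= 1")
        if not (0 <= self.insertion_column <= extein_length):
            raise ValueError(f"element {self.name!r}: insertion column outside extein")
        if self.n_origins < 1 or self.hgt_rate < 0 or self.element_model_scale <= 0:
            raise ValueError(f"element {self.name!r}: invalid rates/origins")


@dataclass
class ScenarioConfig:
    n_taxa: int
    cluster_sizes: list[int]
    birth_rate: float = 1.0
    extein_length: int = 400
    model_name: str = "WAG+G4"
    element_specs: list[ElementSpec] = field(default_factory=list)
    gene_loss_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if sum(self.cluster_sizes) != self.n_taxa:
            raise ValueError("cluster_sizes must sum to n_taxa")
        if self.extein_length < 1 or self.birth_rate <= 0:
            raise ValueError("lengths and rates must be positive")
        if not (0.0 <= self.gene_loss_fraction < 1.0):
            raise ValueError("gene_loss_fraction must be in [0, 1)")
        cols = [e.insertion_column for e in self.element_specs]
        if cols != sorted(cols) or len(set(cols)) != len(cols):
            raise ValueError("element insertion columns must be strictly increasing")
        for e in self.element_specs:
            e.validate(self.extein_length)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["element_specs"] = [ElementSpec(**e) for e in raw.get("element_specs", [])]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass(frozen=True)
class Event:
    kind: str                      # origin | hgt | homing | gene_loss
    element: str
    donor: str                     # taxon, edge label, or "" for origins/losses
    recipient: str                 # edge label (sorted leaf list) or taxon
    time: float


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)

    def add(self, *args, **kwargs) -> None:
        self.events.append(Event(*args, **kwargs))

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def to_records(self) -> list[dict]:
        return [asdict(e) for e in self.events]


@dataclass
class TruthBundle:
    host_tree: dendropy.Tree                       # rooted, ultrametric, timed
    element_trees: dict[str, list[dendropy.Tree]]  # genealogies per origin
    true_site_sets: dict[str, tuple[int, int]]     # half-open alignment blocks
    carrier_sets: dict[str, set[str]]
    event_log: EventLog
    config: ScenarioConfig


@dataclass
class SimulatedScenario:
    truth: TruthBundle
    alignment: Alignment           # true alignment (simulation knows homology)
    sequences: dict[str, str]      # unaligned (gap-free) sequences
    metadata: pd.DataFrame


# ----------------------------------------------------------------- host tree
def _yule(n_taxa: int, birth_rate: float, rng: np.random.Generator) -> dendropy.Tree:
    """Rooted ultrametric pure-birth tree; node ``sim_time`` from the root.

    The process starts with two lineages at the root and, after reaching
    ``n_taxa`` lineages, runs one final Exp(rate * n) epoch, so the expected
    root-to-tip depth is Sum_{k=2..n} 1/(rate*k).
    """
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    root.sim_time = 0.0
    active = []
    for _ in range(2):
        ch = root.new_child()
        active.append(ch)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = rng.integers(len(active))
        nd = active.pop(int(k))
        nd.sim_time = t
        for _ in range(2):
            active.append(nd.new_child())
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    width = len(str(n_taxa))
    leaves_in_order = [nd for nd in tree.preorder_node_iter() if nd in set(active)]
    for i, nd in enumerate(leaves_in_order, start=1):
        nd.sim_time = t
        nd.taxon = ns.require_taxon(label=f"T{i:0{width}d}")
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        nd.edge.length = nd.sim_time - nd.parent_node.sim_time
    tree.is_rooted = True
    return tree


def simulate_host_tree(n_taxa: int, birth_rate: float, seed: int,
                       rooted: bool = False) -> dendropy.Tree:
    """Pure-birth host tree; unrooted (basal trifurcation) unless ``rooted``."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    if n_taxa == 2:
        t = rng.exponential(1.0 / (2 * birth_rate))
        ns = dendropy.TaxonNamespace()
        tree = dendropy.Tree.get(data=f"(T1:{t:.10g},T2:{t:.10g});", schema="newick",
                                 taxon_namespace=ns)
        tree.is_rooted = rooted
        return tree
    tree = _yule(n_taxa, birth_rate, rng)
    if not rooted:
        tree = tree.clone(depth=1)
        tree.deroot()
        tree.is_rooted = False
    return tree


# ------------------------------------------------------------ seq. evolution
def _decode(states: np.ndarray) -> str:
    return "".join(AA_ORDER[s] for s in states)


def evolve_sequences(tree: dendropy.Tree, model: SubstModel, length: int,
                     seed: int | np.random.Generator, scale: float = 1.0,
                     root_states: np.ndarray | None = None) -> dict[str, str]:
    """Simulate sequences along ``tree`` under ``model``.

    The root sequence is drawn from the model's equilibrium frequencies
    (unless given); each site evolves independently with a per-site rate
    drawn from the model's rate mixture; transitions use exp(Q t r).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = model.frequencies
    weights = model.category_weights
    cats = rng.choice(len(weights), size=length, p=weights)
    if root_states is None:
        root_states = rng.choice(20, size=length, p=pi)
    states: dict[int, np.ndarray] = {id(tree.seed_node): np.asarray(root_states)}
    out: dict[str, str] = {}
    if tree.seed_node.is_leaf():  # degenerate single-node genealogy
        out[tree.seed_node.taxon.label] = _decode(states[id(tree.seed_node)])
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        t = (nd.edge.length or 0.0) * scale
        parent_states = states[id(nd.parent_node)]
        if t <= 0:
            child = parent_states.copy()
        else:
            P = model.transition_matrices(t)
            child = np.empty(length, dtype=np.int64)
            u = rng.random(length)
            for c in np.unique(cats):
                idx = np.flatnonzero(cats == c)
                cum = P[c].cumsum(axis=1)
                rowcum = cum[parent_states[idx]]
                child[idx] = (rowcum < u[idx, None]).sum(axis=1)
        states[id(nd)] = child
        if nd.is_leaf():
            out[nd.taxon.label] = _decode(child)
    return out


# ------------------------------------------------------------ element history
def _edge_label(head: dendropy.Node) -> str:
    leaves = sorted(lf.taxon.label for lf in head.leaf_iter())
    return "|".join(leaves)


class _Genealogy:
    """Element transmission genealogy: nodes with parent pointers and times."""

    def __init__(self) -> None:
        self.parent: dict[int, int | None] = {}
        self.time: dict[int, float] = {}
        self.taxon: dict[int, str] = {}
        self._next = 0

    def new_node(self, parent: int | None, time: float, taxon: str | None = None) -> int:
        k = self._next
        self._next += 1
        self.parent[k] = parent
        self.time[k] = time
        if taxon is not None:
            self.taxon[k] = taxon
        return k

    def to_trees(self, scale: float) -> list[dendropy.Tree]:
        """One dendropy tree per origin, leaves = carrier taxa, lengths scaled."""
        leaves = sorted(self.taxon, key=lambda k: self.taxon[k])
        keep: set[int] = set()
        for k in leaves:
            while k is not None and k not in keep:
                keep.add(k)
                k = self.parent[k]
        roots = [k for k in keep if self.parent[k] is None or self.parent[k] not in keep]
        trees = []
        for root in sorted(roots):
            ns = dendropy.TaxonNamespace()
            dnodes: dict[int, dendropy.Node] = {}
            order = sorted((self.time[k], k) for k in keep if self._root_of(k, keep) == root)
            for _, k in order:
                nd = dendropy.Node()
                if k in self.taxon:
                    nd.taxon = ns.require_taxon(label=self.taxon[k])
                p = self.parent[k]
                if p is not None and p in dnodes:
                    dnodes[p].add_child(nd)
                    nd.edge.length = max(self.time[k] - self.time[p], 0.0) * scale
                dnodes[k] = nd
            tree = dendropy.Tree(taxon_namespace=ns, seed_node=dnodes[root])
            tree.suppress_unifurcations()
            tree.is_rooted = True
            trees.append(tree)
        return trees

    def _root_of(self, k: int, keep: set[int]) -> int:
        while self.parent[k] is not None and self.parent[k] in keep:
            k = self.parent[k]
        return k


def apply_element_history(host_tree: dendropy.Tree, spec: ElementSpec,
                          model: SubstModel,
                          rng: np.random.Generator) -> tuple[dict[str, str], EventLog, list[dendropy.Tree]]:
    """Simulate one element's history on a rooted, timed host tree.

    Returns carrier->element-sequence, the event log, and the element
    genealogy (one tree per origin that left surviving carriers).  Homing
    groups receive byte-identical element sequences regardless of their
    hosts' divergence.  Histories leaving fewer than ``spec.min_carriers``
    carriers are redrawn (the simulation is conditioned on the element being
    observable at all).
    """
    n_taxa = sum(1 for _ in host_tree.leaf_node_iter())
    cap = max(spec.max_carrier_fraction * n_taxa, spec.min_carriers)
    for _ in range(100):
        seqs, log, trees = _element_history_once(host_tree, spec, model, rng)
        if spec.min_carriers <= len(seqs) <= cap:
            return seqs, log, trees
    raise RuntimeError(
        f"element {spec.name!r}: no history with {spec.min_carriers}.."
        f"{cap:.0f} carriers in 100 draws"
    )


def _element_history_once(host_tree, spec, model, rng):
    nodes = list(host_tree.preorder_node_iter())
    if not hasattr(nodes[0], "sim_time"):
        raise ValueError("host tree must carry node times (simulate_host_tree(rooted=True))")
    all_taxa = {lf.taxon.label for lf in host_tree.leaf_node_iter()}
    for grp in spec.homing_groups:
        bad = set(grp) - all_taxa
        if bad:
            raise ValueError(f"homing group names unknown taxa: {sorted(bad)}")
    root = host_tree.seed_node
    edges = [nd for nd in nodes if nd is not root]
    lengths = np.array([nd.edge.length for nd in edges])
    labels = {id(nd): _edge_label(nd) for nd in edges}
    t_end = max(nd.sim_time for nd in nodes)

    # fixed events: speciations (internal nodes) and element origins
    origin_idx = rng.choice(len(edges), size=min(spec.n_origins, len(edges)),
                            replace=False, p=lengths / lengths.sum())
    fixed: list[tuple[float, int, str, dendropy.Node]] = []
    for k, nd in enumerate(nodes):
        if nd is root or nd.is_leaf():
            continue
        fixed.append((nd.sim_time, k, "spec", nd))
    for j, ei in enumerate(sorted(int(i) for i in origin_idx)):
        nd = edges[ei]
        t0 = nd.parent_node.sim_time + rng.uniform(0, nd.edge.length)
        fixed.append((t0, len(nodes) + j, "origin", nd))
    fixed.sort()

    gen = _Genealogy()
    log = EventLog()
    carrier: dict[int, int] = {}     # id(edge head) -> genealogy node
    node_by_id = {id(nd): nd for nd in nodes}
    alive: set[int] = {id(ch) for ch in root.child_nodes()}
    t_cur = 0.0

    def run_hgt(until: float) -> None:
        nonlocal t_cur
        while spec.hgt_rate > 0 and carrier:
            dt = rng.exponential(1.0 / (spec.hgt_rate * len(carrier)))
            if t_cur + dt >= until:
                break
            t_cur += dt
            donors = sorted(carrier, key=lambda e: labels[e])
            donor = donors[int(rng.integers(len(donors)))]
            others = sorted((e for e in alive if e != donor), key=lambda e: labels[e])
            if not others:
                continue
            recip = others[int(rng.integers(len(others)))]
            g = gen.new_node(carrier[donor], t_cur)
            carrier[donor] = g
            carrier[recip] = g
            log.add("hgt", spec.name, labels[donor], labels[recip], t_cur)
        t_cur = until

    for t_next, _, kind, nd in fixed:
        run_hgt(t_next)
        if kind == "spec":
            alive.discard(id(nd))
            for ch in nd.child_nodes():
                alive.add(id(ch))
            if id(nd) in carrier:
                g = gen.new_node(carrier.pop(id(nd)), nd.sim_time)
                for ch in nd.child_nodes():
                    carrier[id(ch)] = g
        else:  # origin
            g = gen.new_node(None, t_next)
            carrier[id(nd)] = g
            log.add("origin", spec.name, "", labels[id(nd)], t_next)
    run_hgt(t_end)

    # terminal leaves of the genealogy
    leaf_gen: dict[str, int] = {}
    for eid, g in sorted(carrier.items(), key=lambda kv: labels[kv[0]]):
        nd = node_by_id[eid]
        if nd.is_leaf():
            leaf_gen[nd.taxon.label] = gen.new_node(g, nd.sim_time, taxon=nd.taxon.label)

    # homing sweeps: copy a donor's element verbatim into the whole group.
    # The donor's terminal node becomes the hub; it keeps a zero-length leaf
    # of its own so every group member, donor included, ends as a leaf.
    for grp in spec.homing_groups:
        members = list(grp)
        donor = next((m for m in members if m in leaf_gen), None)
        if donor is None:
            donor = members[0]
            leaf_gen[donor] = gen.new_node(None, t_end, taxon=donor)
            log.add("origin", spec.name, "", donor, t_end)
        hub = leaf_gen[donor]
        del gen.taxon[hub]
        leaf_gen[donor] = gen.new_node(hub, t_end, taxon=donor)
        for m in members:
            if m == donor:
                continue
            if m in leaf_gen:   # replaced by the homing copy
                del gen.taxon[leaf_gen[m]]
            leaf_gen[m] = gen.new_node(hub, t_end, taxon=m)
            log.add("homing", spec.name, donor, m, t_end)

    trees = gen.to_trees(spec.element_model_scale)
    seqs: dict[str, str] = {}
    for k, tr in enumerate(trees):
        sub = evolve_sequences(tr, model, spec.length, rng, scale=1.0)
        seqs.update(sub)
    return seqs, log, trees


# --------------------------------------------------------------- assembly
def build_true_alignment(extein_seqs: dict[str, str],
                         element_blocks: list[tuple[ElementSpec, dict[str, str]]],
                         labels: dict[str, str] | None = None
                         ) -> tuple[Alignment, dict[str, tuple[int, int]]]:
    """Interleave extein residues and element blocks into the true alignment.

    Non-carriers receive gaps across an element's block.  Returns the
    alignment and each element's half-open column interval.
    """
    taxa = sorted(extein_seqs)
    site_sets: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    prev = 0
    offset = 0
    for spec, eseqs in element_blocks:
        col = spec.insertion_column
        for t in taxa:
            rows[t].append(extein_seqs[t][prev:col])
        offset += col - prev
        start = offset
        for t in taxa:
            rows[t].append(eseqs.get(t, "-" * spec.length))
        offset += spec.length
        site_sets[spec.name] = (start, offset)
        prev = col
    for t in taxa:
        rows[t].append(extein_seqs[t][prev:])
    aln_rows = {t: "".join(rows[t]) for t in taxa}
    return Alignment(ids=taxa, rows=aln_rows, labels=dict(labels or {})), site_sets


def simulate_scenario(config: ScenarioConfig) -> SimulatedScenario:
    """Run the full generative model for one scenario configuration."""
    root_rng = np.random.default_rng(config.seed)
    seeds = root_rng.integers(0, 2**31 - 1, size=3 + len(config.element_specs))
    host = simulate_host_tree(config.n_taxa, config.birth_rate, int(seeds[0]), rooted=True)
    model = parse_model_spec(config.model_name)
    extein = evolve_sequences(host, model, config.extein_length, int(seeds[1]))

    # cluster labels follow the tree's leaf order, so clusters are coherent
    leaf_order = [lf.taxon.label for lf in host.leaf_node_iter()]
    labels: dict[str, str] = {}
    pos = 0
    for ci, size in enumerate(config.cluster_sizes):
        name = chr(ord("A") + ci) if ci < 26 else f"C{ci}"
        for t in leaf_order[pos:pos + size]:
            labels[t] = name
        pos += size

    log = EventLog()
    element_blocks: list[tuple[ElementSpec, dict[str, str]]] = []
    element_trees: dict[str, list[dendropy.Tree]] = {}
    carrier_sets: dict[str, set[str]] = {}
    for k, spec in enumerate(config.element_specs):
        rng = np.random.default_rng(int(seeds[3 + k]))
        seqs, elog, trees = apply_element_history(host, spec, model, rng)
        log.events.extend(elog.events)
        element_blocks.append((spec, seqs))
        element_trees[spec.name] = trees
        carrier_sets[spec.name] = set(seqs)

    aln, site_sets = build_true_alignment(extein, element_blocks, labels)

    # gene loss: stratified taxon dropout, emulating the family's sporadic
    # distribution across phage clusters
    if config.gene_loss_fraction > 0:
        loss_rng = np.random.default_rng(int(seeds[2]))
        protected = {m for spec in config.element_specs for g in spec.homing_groups for m in g}
        drop: list[str] = []
        for name in sorted(set(labels.values())):
            members = sorted(t for t in aln.ids if labels[t] == name and t not in protected)
            n_drop = int(round(config.gene_loss_fraction * len(members)))
            if n_drop:
                drop.extend(loss_rng.choice(members, size=n_drop, replace=False))
        for t in sorted(drop):
            log.add("gene_loss", "", "", t, float("inf"))
        aln = aln.subset_rows(set(aln.ids) - set(drop))
        carrier_sets = {k: v & set(aln.ids) for k, v in carrier_sets.items()}

    truth = TruthBundle(host_tree=host, element_trees=element_trees,
                        true_site_sets=site_sets, carrier_sets=carrier_sets,
                        event_log=log, config=config)
    sequences = {t: aln.ungapped(t) for t in aln.ids}
    homing_members = {m: spec.name for spec in config.element_specs
                      for g in spec.homing_groups for m in g}
    meta = pd.DataFrame({
        "phage": aln.ids,
        "cluster": [labels[t] for t in aln.ids],
        "location": [f"shared_site_{homing_members[t]}" if t in homing_members
                     else f"site_{labels[t]}" for t in aln.ids],
    })
    return SimulatedScenario(truth=truth, alignment=aln, sequences=sequences,
                             metadata=meta)


# ------------------------------------------------------------------- output
def write_scenario(scenario: SimulatedScenario, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA/newick/TSV/JSON artifacts; see :func:`read_truth`."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    aln = scenario.alignment
    paths = {
        "alignment": out / "true_alignment.fasta",
        "sequences": out / "sequences.fasta",
        "metadata": out / "metadata.tsv",
        "host_tree": out / "host_tree.nwk",
        "truth": out / "truth.json",
    }
    write_fasta(aln, paths["alignment"])
    unaligned = Alignment(ids=list(aln.ids),
                          rows={t: scenario.sequences[t] for t in aln.ids},
                          aligned=False)
    write_fasta(unaligned, paths["sequences"])
    scenario.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    truth = scenario.truth
    paths["host_tree"].write_text(
        truth.host_tree.as_string(schema="newick", suppress_rooting=True))
    for name, trees in truth.element_trees.items():
        p = out / f"element_{name}.nwk"
        p.write_text("".join(t.as_string(schema="newick", suppress_rooting=True)
                             for t in trees))
        paths[f"element_tree_{name}"] = p
    payload = {
        "config": asdict(truth.config),
        "site_sets": {k: list(v) for k, v in truth.true_site_sets.items()},
        "carrier_sets": {k: sorted(v) for k, v in truth.carrier_sets.items()},
        "events": truth.event_log.to_records(),
    }
    paths["truth"].write_text(json.dumps(payload, indent=2) + "\n")
    return paths


def read_truth(path: str | Path) -> dict:
    """Read back the truth JSON written by :func:`write_scenario`."""
    raw = json.loads(Path(path).read_text())
    raw["carrier_sets"] = {k: set(v) for k, v in raw["carrier_sets"].items()}
    raw["site_sets"] = {k: tuple(v) for k, v in raw["site_sets"].items()}
    return raw
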
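"""Phylogenetic-incongruence and transfer analysis for insertion elements.

Vertically inherited elements accumulate divergence in step with their host
proteins, so element-vs-extein pairwise distances correlate; horizontally
transferred elements decouple the two, and a recent homing sweep leaves
byte-identical element sequences inside hosts that diverged long ago.  This
module quantifies those signatures: paired-distance R² (with leave-one-out
outlier exclusion and a Mantel permutation diagnostic), identical-element
invasion groups, and a constrained-clan topology-test suite asking whether
carriers (or phage clusters) could form a clan in the host phylogeny.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr

from . import alnio, elementscan
from .phylocore import (DistanceMatrix, distance_matrix, ml_search, nj_tree,
                        parse_model_spec, patristic_distances)
from .topotest import DEFAULT_SCALES, TopoTestResult, test_suite


class InsufficientOverlapError(ValueError):
    pass


class DegenerateDistancesError(ValueError):
    pass


@dataclass
class PairedDistances:
    """Element and extein distances for every unordered shared taxon pair."""

    pairs: list[tuple[str, str]]
    element_d: np.ndarray
    extein_d: np.ndarray


def paired_distances(dm_element: DistanceMatrix,
                     dm_extein: DistanceMatrix) -> PairedDistances:
    shared = sorted(set(dm_element.taxa) & set(dm_extein.taxa))
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared taxa; need >= 3"
        )
    pairs = list(combinations(shared, 2))
    el = np.array([dm_element.get(a, b) for a, b in pairs])
    ex = np.array([dm_extein.get(a, b) for a, b in pairs])
    return PairedDistances(pairs, el, ex)


def distance_r2(pairs: PairedDistances) -> float:
    """Squared Pearson correlation of element vs extein pair distances."""
    if len(pairs.pairs) < 3:
        raise InsufficientOverlapError("need at least 3 pairs")
    if np.ptp(pairs.element_d) == 0 or np.ptp(pairs.extein_d) == 0:
        raise DegenerateDistancesError("zero variance in one distance set")
    r, _ = pearsonr(pairs.element_d, pairs.extein_d)
    return float(r * r)


def leave_one_out_r2(dm_element: DistanceMatrix, dm_extein: DistanceMatrix,
                     exclude: str) -> float:
    """R² over pairs not involving ``exclude``."""
    shared = set(dm_element.taxa) & set(dm_extein.taxa)
    keep = shared - {exclude}
    if len(keep) < 3:
        raise InsufficientOverlapError("exclusion leaves fewer than 3 taxa")
    return distance_r2(paired_distances(dm_element.subset(keep),
                                        dm_extein.subset(keep)))


def leave_one_out_table(dm_element: DistanceMatrix,
                        dm_extein: DistanceMatrix) -> pd.Series:
    """R² after excluding each shared taxon in turn (max = likeliest outlier)."""
    shared = sorted(set(dm_element.taxa) & set(dm_extein.taxa))
    out = {}
    for t in shared:
        try:
            out[t] = leave_one_out_r2(dm_element, dm_extein, t)
        except (InsufficientOverlapError, DegenerateDistancesError):
            out[t] = np.nan
    return pd.Series(out, name="r2_without")


def mantel_pvalue(pairs: PairedDistances, n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value for the matrix correlation (taxa relabelled)."""
    taxa = sorted({t for p in pairs.pairs for t in p})
    n = len(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for (a, b), de, dx in zip(pairs.pairs, pairs.element_d, pairs.extein_d):
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = de
        B[idx[a], idx[b]] = B[idx[b], idx[a]] = dx
    iu = np.triu_indices(n, 1)
    r_obs = abs(pearsonr(A[iu], B[iu])[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r = abs(pearsonr(A[np.ix_(p, p)][iu], B[iu])[0])
        hits += (r >= r_obs)
    return float((hits + 1) / (n_perm + 1))


# ------------------------------------------------------------ invasion groups
@dataclass
class InvasionGroup:
    taxa: frozenset[str]
    max_element_p_distance: float
    mean_extein_distance: float


def _p_distance(a: str, b: str) -> float:
    if len(a) != len(b):
        return 1.0
    if not a:
        return 0.0
    diff = sum(x != y for x, y in zip(a, b))
    return diff / len(a)


def detect_recent_invasions(element_sequences: dict[str, str],
                            dm_extein: DistanceMatrix,
                            identity_eps: float = 0.0,
                            min_group: int = 2,
                            min_extein_divergence: float = 0.1) -> list[InvasionGroup]:
    """Groups of (near-)identical elements inside diverged hosts.

    Builds a graph on carriers with edges where the element p-distance is
    <= ``identity_eps``; connected components of >= ``min_group`` members
    whose mean pairwise extein distance is >= ``min_extein_divergence`` are
    reported — the signature of a recent homing sweep long after the hosts
    diverged.
    """
    taxa = sorted(set(element_sequences) & set(dm_extein.taxa))
    g = nx.Graph()
    g.add_nodes_from(taxa)
    for a, b in combinations(taxa, 2):
        if _p_distance(element_sequences[a], element_sequences[b]) <= identity_eps:
            g.add_edge(a, b)
    out = []
    for comp in nx.connected_components(g):
        if len(comp) < min_group:
            continue
        members = sorted(comp)
        el_d = [_p_distance(element_sequences[a], element_sequences[b])
                for a, b in combinations(members, 2)]
        ex_d = [dm_extein.get(a, b) for a, b in combinations(members, 2)]
        if np.mean(ex_d) >= min_extein_divergence:
            out.append(InvasionGroup(
                taxa=frozenset(members),
                max_element_p_distance=float(max(el_d)),
                mean_extein_distance=float(np.mean(ex_d)),
            ))
    return sorted(out, key=lambda grp: sorted(grp.taxa))


def element_deep_split(element_tree: dendropy.Tree) -> tuple[set, set]:
    """The two sides of the longest internal edge of an element tree.

    Reported descriptively for elements whose copies fall into two distinct
    sequence families; no test is attached.
    """
    taxa = {lf.taxon.label for lf in element_tree.leaf_node_iter()}
    best, best_len = None, -1.0
    for nd in element_tree.postorder_node_iter():
        if nd.is_leaf() or nd is element_tree.seed_node:
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        if 2 <= len(side) <= len(taxa) - 2 and (nd.edge.length or 0) > best_len:
            best, best_len = side, nd.edge.length or 0
    if best is None:
        return taxa, set()
    return best, taxa - best


# -------------------------------------------------------------- clan suite
@dataclass
class ConstraintSuiteResult:
    table: pd.DataFrame
    topo: TopoTestResult
    trees: dict[str, dendropy.Tree]
    unconstrained_lnl: float


def clan_suite(data, groupings: dict[str, set], model, n_reps: int = 10_000,
               scales=DEFAULT_SCALES, seed: int = 0,
               include_joint: bool = False) -> ConstraintSuiteResult:
    """Constrained-clan topology-test suite over a partition.

    For each named taxon group, the best ML tree constrained to keep that
    group as a clan is compared against the unconstrained ML tree with the
    KH, SH and AU tests.  With ``include_joint`` an additional hypothesis
    constrains all groups simultaneously.  Groups equal to the full taxon
    set (degenerate: identical to the unconstrained search) are flagged.
    """
    aln = data.alignment if hasattr(data, "alignment") else data
    taxa = set(aln.ids)
    for name, grp in groupings.items():
        if not set(grp) <= taxa:
            raise ValueError(f"group {name!r} has taxa outside the partition")
        if len(grp) < 2:
            raise ValueError(f"group {name!r} must have >= 2 taxa")
    ml_tree, ml_lnl = ml_search(aln, model, seed=seed)
    trees = {"ml": ml_tree}
    degenerate = set()
    for name, grp in groupings.items():
        if set(grp) >= taxa or len(taxa - set(grp)) <= 1:
            degenerate.add(name)
            trees[name] = ml_tree
            continue
        trees[name], _ = ml_search(aln, model, seed=seed, constraint=set(grp),
                                   start_tree=None)
    if include_joint:
        clans = [set(g) for n, g in groupings.items() if n not in degenerate]
        trees["all_groups"], _ = ml_search(aln, model, seed=seed, constraint=clans)
    topo = test_suite(aln, model, trees, n_reps=n_reps, scales=scales, seed=seed)
    recs = []
    for row in topo.rows:
        grp = groupings.get(row.tree_id, set())
        recs.append({
            "hypothesis": row.tree_id,
            "n_constrained": len(grp),
            "lnl": row.lnl,
            "delta_lnl": row.delta_lnl,
            "p_kh": row.p_kh,
            "p_sh": row.p_sh,
            "p_au": row.p_au,
            "rejected": row.rejected,
            "degenerate": row.tree_id in degenerate,
        })
    return ConstraintSuiteResult(table=pd.DataFrame(recs), topo=topo,
                                 trees=trees, unconstrained_lnl=ml_lnl)


# ------------------------------------------------------------------ pipeline
@dataclass
class TransferReport:
    elements: pd.DataFrame              # per-element R², Mantel p, flags
    leave_one_out: dict[str, pd.Series]
    invasion_groups: dict[str, list[InvasionGroup]]
    suite: ConstraintSuiteResult | None = None
    extras: dict = field(default_factory=dict)


def analyze_element(element: elementscan.InsertionElement, alignment: alnio.Alignment,
                    model, min_span: float = 0.5, use_patristic: bool = False,
                    seed: int = 0) -> dict:
    """Distance matrices, R², leave-one-out and invasion groups for one element.

    Distances are direct pairwise ML estimates by default; with
    ``use_patristic`` they are path lengths on NJ trees built from them.
    """
    site_sets = alnio.define_site_sets(alignment, [element])
    extein_ss = next(s for s in site_sets if s.name == "extein")
    element_ss = next(s for s in site_sets if s.name == element.name)
    el_part = alnio.extract_partition(alignment, element_ss, carriers_only=True,
                                      min_span=min_span)
    carriers = set(el_part.alignment.ids)
    ext_part = alnio.extract_partition(alignment, extein_ss)
    ext_carriers = ext_part.alignment.subset_rows(carriers)
    dm_el = distance_matrix(el_part.alignment, model)
    dm_ex = distance_matrix(ext_carriers, model)
    if use_patristic and len(carriers) >= 4:
        dm_el = patristic_distances(nj_tree(dm_el))
        dm_ex = patristic_distances(nj_tree(dm_ex))
    pairs = paired_distances(dm_el, dm_ex)
    r2 = distance_r2(pairs)
    loo = leave_one_out_table(dm_el, dm_ex)
    inv = detect_recent_invasions(
        elementscan.extract_element_sequences(element, alignment), dm_ex)
    return {
        "element": element,
        "carriers": carriers,
        "dm_element": dm_el,
        "dm_extein": dm_ex,
        "pairs": pairs,
        "r2": r2,
        "mantel_p": mantel_pvalue(pairs, seed=seed),
        "leave_one_out": loo,
        "invasion_groups": inv,
    }


def run_pipeline(config: dict | str | Path) -> dict:
    """End-to-end orchestration: scan -> partition -> trees -> tests -> report.

    ``config`` is a YAML path or dict with keys: ``alignment`` (FASTA),
    ``metadata`` (TSV: phage, cluster, location), ``out_dir``, ``model``
    (spec string, default WAG+G4), ``seed``, optional ``scan`` parameter
    overrides, ``n_reps``/``scales`` for the topology tests, and
    ``run_clan_suite`` (bool).  All intermediates are written under
    ``out_dir``; returns the report dict (also written as JSON).
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    try:
        aln_path = config["alignment"]
        out_dir = Path(config["out_dir"])
    except KeyError as exc:
        raise ValueError(f"pipeline config missing key: {exc}") from exc
    seed = int(config.get("seed", 0))
    model = parse_model_spec(config.get("model", "WAG+G4"))
    out_dir.mkdir(parents=True, exist_ok=True)

    labels = {}
    meta = None
    if config.get("metadata"):
        meta = alnio.read_metadata(config["metadata"])
        labels = dict(zip(meta["phage"], meta["cluster"]))
    aln = alnio.read_fasta(aln_path, labels=labels)

    stage = "scan"
    try:
        elements = elementscan.scan_insertions(aln, **config.get("scan", {}))
        site_sets = alnio.define_site_sets(aln, elements)
        alnio.write_site_sets(site_sets, out_dir / "site_sets.tsv")
        alnio.write_carrier_report(elements, out_dir / "elements.json")

        stage = "element analysis"
        element_rows = []
        loo = {}
        invasions = {}
        for el in elements:
            res = analyze_element(el, aln, model, seed=seed)
            res["dm_element"].to_tsv(out_dir / f"dm_{el.name}.tsv")
            res["dm_extein"].to_tsv(out_dir / f"dm_extein_{el.name}.tsv")
            pd.DataFrame({
                "pair": ["|".join(p) for p in res["pairs"].pairs],
                "element_d": res["pairs"].element_d,
                "extein_d": res["pairs"].extein_d,
            }).to_csv(out_dir / f"scatter_{el.name}.tsv", sep="\t", index=False)
            loo[el.name] = res["leave_one_out"]
            invasions[el.name] = res["invasion_groups"]
            element_rows.append({
                "element": el.name,
                "block_start": el.block[0],
                "block_end": el.block[1],
                "n_carriers": len(el.carriers),
                "r2": res["r2"],
                "mantel_p": res["mantel_p"],
                "n_invasion_groups": len(res["invasion_groups"]),
            })
        elements_df = pd.DataFrame(element_rows)
        elements_df.to_csv(out_dir / "element_r2.tsv", sep="\t", index=False)

        suite = None
        if config.get("run_clan_suite", False):
            stage = "clan suite"
            extein_ss = next(s for s in site_sets if s.name == "extein")
            ext_part = alnio.extract_partition(aln, extein_ss)
            groupings: dict[str, set] = {}
            if labels:
                for cl in sorted(set(labels.values())):
                    members = {t for t in aln.ids if labels.get(t) == cl}
                    if 2 <= len(members) <= len(aln.ids) - 2:
                        groupings[f"cluster_{cl}"] = members
            for el in elements:
                if 2 <= len(el.carriers) <= len(aln.ids) - 2:
                    groupings[f"{el.name}_carriers"] = set(el.carriers)
            suite = clan_suite(ext_part.alignment, groupings, model,
                               n_reps=int(config.get("n_reps", 10_000)),
                               seed=seed, include_joint=len(groupings) > 1)
            suite.table.to_csv(out_dir / "clan_suite.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = {
        "seed": seed,
        "model": model.spec_string,
        "n_sequences": aln.n_seqs,
        "n_columns": aln.n_columns,
        "elements": element_rows,
        "invasion_groups": {
            name: [{"taxa": sorted(g.taxa),
                    "max_element_p_distance": g.max_element_p_distance,
                    "mean_extein_distance": g.mean_extein_distance}
                   for g in groups]
            for name, groups in invasions.items()
        },
        "clan_suite": suite.table.to_dict(orient="records") if suite is not None else None,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
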
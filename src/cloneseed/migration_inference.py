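"""Parsimonious migration histories on clone trees.

Each tumour (the primary and every metastasis) is a possible label for the
vertices of a *refined* clone tree: the clone tree augmented with one
observation leaf per (cluster, tumour) where the cluster is detected, and
optionally with unlabeled intermediate vertices that resolve polytomies.
Observation-leaf labels are fixed; the root is fixed to the primary.  A tree
edge whose endpoints carry different labels is a migration of the child
endpoint's cluster from the source label to the target label.

The labeling minimises, lexicographically, the number of migrations mu, the
number of comigrations gamma (distinct ordered source-target tumour pairs)
and the number of distinct source tumours, subject to the seeding model:

* ``primary_only``   — every migration starts at the primary;
* ``single_source``  — each metastasis receives migrations from exactly one
  source tumour (solved exactly by branch-and-bound over per-metastasis
  source assignments with a Sankoff relaxation bound);
* ``multi_source``   — unconstrained sources.

Migrations into the primary are never allowed: the primary is resected
before metastatic relapse, so reseeding is not modelled.  The search is a
dynamic program over tumour labels per vertex (Sankoff-style), exact for up
to 12 tumours; beyond that the single-source model falls back to filtering
enumerated multi-source optima.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .cohort_model import CloneTree

log = logging.getLogger("cloneseed")

INF = float("inf")
SEEDING_MODELS = ("primary_only", "single_source", "multi_source")

#: Cap on enumerated minimum-migration labelings when optimising the
#: secondary criteria; exact below the cap, deterministic always.
MAX_OPTIMAL_LABELINGS = 20_000


# --------------------------------------------------------------------------
# Refined tree
# --------------------------------------------------------------------------

@dataclass
class RefinedTree:
    """Clone tree plus observation leaves and optional intermediates.

    Node ids are tuples: ``('c', cluster)`` for cluster vertices,
    ``('o', cluster, tumour)`` for observation leaves (label fixed to the
    tumour) and ``('x', cluster, k)`` for inserted polytomy-resolution
    vertices (free label, genotype of the parent cluster).
    """

    nodes: list[tuple]
    parent: dict[tuple, tuple]
    fixed_label: dict[tuple, str]
    root: tuple

    def children(self) -> dict[tuple, list[tuple]]:
        out: dict[tuple, list[tuple]] = {n: [] for n in self.nodes}
        for child, par in self.parent.items():
            out[par].append(child)
        for kids in out.values():
            kids.sort(key=repr)
        return out

    @staticmethod
    def cluster_of(node: tuple) -> str:
        return node[1]

    def copy(self) -> "RefinedTree":
        return RefinedTree(
            nodes=list(self.nodes),
            parent=dict(self.parent),
            fixed_label=dict(self.fixed_label),
            root=self.root,
        )


def build_refined_tree(
    tree: CloneTree,
    presence_by_tumour: dict[str, set[str]],
    primary: str,
) -> RefinedTree:
    """Attach one observation leaf per tumour in which a cluster is
    detected.  The root cluster vertex is fixed to the primary."""
    nodes: list[tuple] = []
    parent: dict[tuple, tuple] = {}
    fixed: dict[tuple, str] = {}
    for cid in sorted(tree.nodes):
        nodes.append(("c", cid))
    for cid, par in tree.parent.items():
        parent[("c", cid)] = ("c", par)
    for cid in sorted(tree.nodes):
        for tumour in sorted(presence_by_tumour.get(cid, ())):
            leaf = ("o", cid, tumour)
            nodes.append(leaf)
            parent[leaf] = ("c", cid)
            fixed[leaf] = tumour
    root = ("c", tree.root)
    fixed[root] = primary
    return RefinedTree(nodes=nodes, parent=parent, fixed_label=fixed, root=root)


# --------------------------------------------------------------------------
# Sankoff machinery
# --------------------------------------------------------------------------

def _post_order(refined: RefinedTree) -> list[tuple]:
    kids = refined.children()
    order: list[tuple] = []
    stack = [(refined.root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
        else:
            stack.append((node, True))
            for c in kids[node]:
                stack.append((c, False))
    return order


def _sankoff_tables(refined, labels, allowed):
    """Bottom-up minimum-migration tables M[node][label]."""
    kids = refined.children()
    M: dict[tuple, dict[str, float]] = {}
    for node in _post_order(refined):
        fixed = refined.fixed_label.get(node)
        row: dict[str, float] = {}
        for lab in labels:
            if fixed is not None and lab != fixed:
                row[lab] = INF
                continue
            total = 0.0
            for child in kids[node]:
                best = INF
                for lab_c, sub in M[child].items():
                    if sub == INF:
                        continue
                    cost = allowed(lab, lab_c)
                    if cost is None:
                        continue
                    best = min(best, sub + cost)
                total += best
                if total == INF:
                    break
            row[lab] = total
        M[node] = row
    return M


def _enumerate_optimal(refined, labels, allowed, M, cap=MAX_OPTIMAL_LABELINGS):
    """All labelings achieving the minimum migration count (up to ``cap``),
    in deterministic order."""
    kids = refined.children()
    root = refined.root
    root_lab = refined.fixed_label[root]
    if M[root][root_lab] == INF:
        return []

    results: list[dict] = []
    assignment: dict[tuple, str] = {}
    truncated = [False]

    def visit(node, lab, cont):
        """Assign ``lab`` to ``node``, branch over optimal child labels,
        then call ``cont`` for the remainder of the tree."""
        if len(results) >= cap:
            truncated[0] = True
            return
        assignment[node] = lab
        children = kids[node]

        def child_product(i):
            if len(results) >= cap:
                return
            if i == len(children):
                cont()
                return
            child = children[i]
            cands = [
                lc
                for lc in labels
                if M[child][lc] != INF and allowed(lab, lc) is not None
            ]
            target = min(M[child][lc] + allowed(lab, lc) for lc in cands)
            for lc in cands:
                if M[child][lc] + allowed(lab, lc) == target:
                    visit(child, lc, lambda: child_product(i + 1))

        child_product(0)
        del assignment[node]

    visit(root, root_lab, lambda: results.append(dict(assignment)))
    if truncated[0]:
        log.info("optimal-labeling enumeration truncated at %d", cap)
    return results


# --------------------------------------------------------------------------
# Histories
# --------------------------------------------------------------------------

@dataclass
class MigrationHistory:
    model: str
    feasible: bool
    migrations: list[tuple[str, str, str]]  # (source, target, cluster)
    n_migrations: int
    n_comigrations: int
    labels: dict[tuple, str] = field(default_factory=dict)
    seeded_by: dict[str, str] = field(default_factory=dict)  # met -> source kind
    mu_by_model: dict[str, int | None] = field(default_factory=dict)
    refined: RefinedTree | None = None


def _observed_tumours(refined) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for node, lab in refined.fixed_label.items():
        if node[0] == "o":
            out.setdefault(RefinedTree.cluster_of(node), set()).add(lab)
    return out


def _evaluate_labeling(refined, labeling, primary, observed):
    migrations = []
    for child, par in refined.parent.items():
        a, b = labeling[par], labeling[child]
        if a != b:
            migrations.append((a, b, RefinedTree.cluster_of(child)))
    migrations.sort()
    gamma = len({(a, b) for a, b, _ in migrations})
    sources = len({a for a, _, _ in migrations})
    # a cluster vertex labelled with a tumour its mutations were never
    # detected in contradicts its own observation leaves
    inconsistent = sum(
        1
        for node, lab in labeling.items()
        if node[0] == "c"
        and node[1] in observed
        and lab not in observed[node[1]]
    )
    n_primary_internal = sum(
        1
        for node, lab in labeling.items()
        if node[0] in ("c", "x") and lab == primary
    )
    return migrations, gamma, sources, inconsistent, n_primary_internal


def _allowed_fn(model, primary, source_map=None):
    """Transition-cost function for a parent->child label change
    (None = forbidden)."""

    def allowed(a, b):
        if a == b:
            return 0.0
        if b == primary:
            return None  # never a migration into the primary
        if model == "primary_only" and a != primary:
            return None
        if source_map is not None and source_map.get(b, a) != a:
            return None
        return 1.0

    return allowed


def _summarise_seeding(hist: MigrationHistory, primary: str) -> None:
    incoming: dict[str, set[str]] = {}
    for a, b, _ in hist.migrations:
        incoming.setdefault(b, set()).add(a)
    for target, sources in sorted(incoming.items()):
        kinds = {"primary" if s == primary else "metastasis" for s in sources}
        hist.seeded_by[target] = kinds.pop() if len(kinds) == 1 else "both"


def _best_history(refined, labels, allowed, primary, model):
    M = _sankoff_tables(refined, labels, allowed)
    root_lab = refined.fixed_label[refined.root]
    mu = M[refined.root][root_lab]
    if mu == INF:
        return None
    best = None
    best_key = None
    observed = _observed_tumours(refined)
    for lab in _enumerate_optimal(refined, labels, allowed, M):
        migrations, gamma, sources, inconsistent, n_prim = _evaluate_labeling(
            refined, lab, primary, observed
        )
        key = (
            gamma,
            inconsistent,
            sources,
            -n_prim,
            tuple(lab[n] for n in sorted(lab, key=repr)),
        )
        if best_key is None or key < best_key:
            best_key = key
            best = (lab, migrations, gamma)
    lab, migrations, gamma = best
    hist = MigrationHistory(
        model=model,
        feasible=True,
        migrations=migrations,
        n_migrations=int(mu),
        n_comigrations=gamma,
        labels=lab,
        refined=refined,
    )
    _summarise_seeding(hist, primary)
    return hist


def _single_source_ok(migrations) -> bool:
    incoming: dict[str, set[str]] = {}
    for a, b, *_ in migrations:
        incoming.setdefault(b, set()).add(a)
    return all(len(s) == 1 for s in incoming.values())


def _single_source_exact(refined, labels, primary, mets):
    """Branch and bound over per-metastasis source assignments.

    The relaxation (unassigned metastases accept any source) is the plain
    multi-source Sankoff bound, which is admissible; assignment proceeds in
    sorted metastasis order with the primary tried first.
    """
    relaxed = _best_history(
        refined, labels, _allowed_fn("multi_source", primary), primary,
        "single_source",
    )
    if relaxed is None:
        return None
    if _single_source_ok(relaxed.migrations):
        return relaxed
    best = {"key": (INF, INF), "hist": None}
    order = sorted(mets)
    tumours = [primary] + sorted(mets)

    def bound(partial):
        allowed = _allowed_fn("multi_source", primary, source_map=partial)
        M = _sankoff_tables(refined, labels, allowed)
        return M[refined.root][refined.fixed_label[refined.root]]

    def search(i, partial):
        if i == len(order):
            allowed = _allowed_fn("multi_source", primary, source_map=partial)
            hist = _best_history(
                refined, labels, allowed, primary, "single_source"
            )
            if hist is None:
                return
            key = (hist.n_migrations, hist.n_comigrations)
            if key < best["key"]:
                best["key"] = key
                best["hist"] = hist
            return
        met = order[i]
        for src in tumours:
            if src == met:
                continue
            partial[met] = src
            # equal-mu branches stay open so gamma ties resolve exactly
            if bound(partial) <= best["key"][0]:
                search(i + 1, partial)
            del partial[met]

    search(0, {})
    return best["hist"]


def infer_history(
    tree: CloneTree,
    presence_by_tumour: dict[str, set[str]],
    primary: str,
    model: str = "multi_source",
    resolve: bool = True,
) -> MigrationHistory:
    """Infer the most parsimonious migration history under a seeding model.

    ``presence_by_tumour`` maps each cluster to the tumours in which it is
    detected (typically extant subclones only).  Returns a history with
    ``feasible=False`` when no labeling satisfies the model (callers
    escalate to a richer model).
    """
    if model not in SEEDING_MODELS:
        raise ValueError(f"unknown seeding model {model!r}")
    tumours = sorted(
        {t for ts in presence_by_tumour.values() for t in ts} | {primary}
    )
    mets = [t for t in tumours if t != primary]
    refined = build_refined_tree(tree, presence_by_tumour, primary)
    if resolve:
        refined = resolve_polytomies(refined, tumours, primary, model)

    if model == "single_source":
        if len(tumours) > 12:
            log.warning(
                "%d tumours exceeds the exact single-source guard; "
                "filtering multi-source optima instead", len(tumours),
            )
            hist = _best_history(
                refined, tumours, _allowed_fn("multi_source", primary),
                primary, "single_source",
            )
            if hist is not None and _single_source_ok(hist.migrations):
                return hist
            hist = None
        else:
            hist = _single_source_exact(refined, tumours, primary, mets)
    else:
        hist = _best_history(
            refined, tumours, _allowed_fn(model, primary), primary, model
        )
    if hist is None:
        return MigrationHistory(
            model=model, feasible=False, migrations=[],
            n_migrations=0, n_comigrations=0,
        )
    hist.model = model
    return hist


# --------------------------------------------------------------------------
# Polytomy resolution
# --------------------------------------------------------------------------

def _mu_of(refined, tumours, primary, model):
    # The single-source constraint does not change which polytomy groupings
    # help, so its relaxation is used while resolving.
    eff = "multi_source" if model == "single_source" else model
    M = _sankoff_tables(refined, tumours, _allowed_fn(eff, primary))
    return M[refined.root][refined.fixed_label[refined.root]]


def _all_binary_groupings(children):
    """All rooted binary shapes over the children, as nested two-element
    lists with original node ids at the leaves."""
    if len(children) == 2:
        return [[children[0], children[1]]]
    shapes = []
    last = children[-1]

    def attach(shape):
        yield [shape, last]
        if isinstance(shape, list):
            left, right = shape
            for g in attach(left):
                yield [g, right]
            for g in attach(right):
                yield [left, g]

    for s in _all_binary_groupings(children[:-1]):
        shapes.extend(attach(s))
    return shapes


def _apply_shape(tree: RefinedTree, node, shape, counter) -> RefinedTree:
    """Replace ``node``'s child list with a binary shape of intermediates."""
    out = tree.copy()
    cid = RefinedTree.cluster_of(node)

    def build(s, parent):
        if not isinstance(s, list):
            out.parent[s] = parent
            return
        x = ("x", cid, next(counter))
        out.nodes.append(x)
        out.parent[x] = parent
        build(s[0], x)
        build(s[1], x)

    build(shape[0], node)
    build(shape[1], node)
    return out


def _prune_intermediates(refined: RefinedTree, tumours, primary, model):
    """Remove inserted vertices that do not contribute: contract any
    intermediate whose removal leaves the migration count unchanged."""
    out = refined.copy()
    base = _mu_of(out, tumours, primary, model)
    changed = True
    while changed:
        changed = False
        kids = out.children()
        for n in sorted((m for m in out.nodes if m[0] == "x"), key=repr):
            cand = out.copy()
            par = cand.parent[n]
            for c in kids[n]:
                cand.parent[c] = par
            cand.nodes.remove(n)
            del cand.parent[n]
            if _mu_of(cand, tumours, primary, model) <= base:
                out = cand
                changed = True
                break
    return out


def resolve_polytomies(
    refined: RefinedTree,
    tumours: list[str],
    primary: str,
    model: str = "multi_source",
    max_degree_exhaustive: int = 6,
) -> RefinedTree:
    """Insert unlabeled intermediate vertices at multifurcations when doing
    so strictly reduces the migration count.

    Exhaustive over binary refinements for degree <= ``max_degree_exhaustive``
    (all rooted binary shapes over the children); greedy pairwise joins
    beyond.  Intermediates that do not reduce the count are contracted, so
    the output collapses back to the input tree when they are removed.
    """
    counter = itertools.count()
    current = refined.copy()
    base_mu = _mu_of(current, tumours, primary, model)
    if base_mu == INF:
        return current

    changed = True
    while changed:
        changed = False
        kids = current.children()
        polytomies = sorted(
            (n for n in current.nodes
             if n[0] in ("c", "x") and len(kids[n]) > 2),
            key=repr,
        )
        for node in polytomies:
            children = kids[node]
            if len(children) <= max_degree_exhaustive:
                cand = _best_exhaustive_resolution(
                    current, node, children, tumours, primary, model, counter
                )
            else:
                cand = _greedy_resolution(
                    current, node, children, tumours, primary, model, counter
                )
            if cand is not None and cand[1] < base_mu:
                current, base_mu = cand
                changed = True
                break
    return _prune_intermediates(current, tumours, primary, model)


def _best_exhaustive_resolution(
    tree, node, children, tumours, primary, model, counter
):
    best = None
    for shape in _all_binary_groupings(list(children)):
        cand = _apply_shape(tree, node, shape, counter)
        mu = _mu_of(cand, tumours, primary, model)
        if best is None or mu < best[1]:
            best = (cand, mu)
    return best


def _greedy_resolution(tree, node, children, tumours, primary, model, counter):
    """Repeated best pairwise join of the polytomy's children."""
    current = tree
    current_children = list(children)
    base_mu = _mu_of(current, tumours, primary, model)
    improved = False
    while len(current_children) > 2:
        best = None
        for i, j in itertools.combinations(range(len(current_children)), 2):
            cand = current.copy()
            x = ("x", RefinedTree.cluster_of(node), next(counter))
            cand.nodes.append(x)
            cand.parent[x] = node
            cand.parent[current_children[i]] = x
            cand.parent[current_children[j]] = x
            mu = _mu_of(cand, tumours, primary, model)
            if best is None or mu < best[3]:
                best = (cand, (i, j), x, mu)
        cand, (i, j), x, mu = best
        if mu >= base_mu:
            break
        current, base_mu, improved = cand, mu, True
        current_children = [
            c for k, c in enumerate(current_children) if k not in (i, j)
        ] + [x]
    return (current, base_mu) if improved else None


# --------------------------------------------------------------------------
# Model selection, reclassification, ensemble probabilities
# --------------------------------------------------------------------------

def select_seeding_model(
    tree: CloneTree,
    presence_by_tumour: dict[str, set[str]],
    primary: str,
    resolve: bool = True,
) -> MigrationHistory:
    """Run the three seeding models and keep the smallest migration count,
    breaking ties toward the simpler model."""
    histories: dict[str, MigrationHistory] = {}
    mu_by_model: dict[str, int | None] = {}
    for model in SEEDING_MODELS:
        h = infer_history(tree, presence_by_tumour, primary, model, resolve)
        histories[model] = h
        mu_by_model[model] = h.n_migrations if h.feasible else None
    best = None
    for model in SEEDING_MODELS:  # simpler models first: ties stay simple
        h = histories[model]
        if h.feasible and (best is None or h.n_migrations < best.n_migrations):
            best = h
    if best is None:
        raise RuntimeError("no feasible migration history under any model")
    best.mu_by_model = mu_by_model
    return best


def reclassify_shared(
    history: MigrationHistory, clonality: dict[str, str], primary: str
) -> dict[str, str]:
    """Metastasis-unique clusters that the parsimonious labeling places in
    the primary become shared subclonal; everything else is unchanged."""
    primary_labelled = {
        RefinedTree.cluster_of(node)
        for node, lab in history.labels.items()
        if node[0] in ("c", "x") and lab == primary
    }
    out = dict(clonality)
    for cid, cls in clonality.items():
        if cls == "metastasis_unique" and cid in primary_labelled:
            out[cid] = "shared_subclonal"
    return out


def migration_probabilities(
    trees: list[CloneTree],
    presence_by_tumour: dict[str, set[str]],
    primary: str,
    model: str = "auto",
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str, str], float]]:
    """Fraction of ensemble solutions containing each migration.

    Identity is the (source, target) tumour pair; cluster-level fractions
    are also returned.  ``model='auto'`` selects the most parsimonious
    model per tree.
    """
    if not trees:
        raise ValueError("empty tree ensemble")
    pair_counts: dict[tuple[str, str], int] = {}
    trip_counts: dict[tuple[str, str, str], int] = {}
    for tree in trees:
        if model == "auto":
            hist = select_seeding_model(tree, presence_by_tumour, primary)
        else:
            hist = infer_history(tree, presence_by_tumour, primary, model)
        if not hist.feasible:
            continue
        for pair in {(a, b) for a, b, _ in hist.migrations}:
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
        for trip in set(hist.migrations):
            trip_counts[trip] = trip_counts.get(trip, 0) + 1
    n = len(trees)
    return (
        {k: v / n for k, v in sorted(pair_counts.items())},
        {k: v / n for k, v in sorted(trip_counts.items())},
    )


def seeded_by_at_threshold(
    pair_probs: dict[tuple[str, str], float],
    primary: str,
    threshold: float,
) -> dict[str, str]:
    """Recompute each metastasis's seeding-source summary keeping only
    migrations at or above a probability threshold."""
    incoming: dict[str, set[str]] = {}
    for (a, b), p in pair_probs.items():
        if p >= threshold:
            incoming.setdefault(b, set()).add(a)
    out = {}
    for target, sources in sorted(incoming.items()):
        kinds = {"primary" if s == primary else "metastasis" for s in sources}
        out[target] = kinds.pop() if len(kinds) == 1 else "both"
    return out


# --------------------------------------------------------------------------
# Brute-force oracle (testing aid)
# --------------------------------------------------------------------------

def brute_force_history(
    refined: RefinedTree,
    tumours: list[str],
    primary: str,
    model: str,
) -> tuple[int, int] | None:
    """Exhaustive minimum (mu, gamma) over all labelings of the refined
    tree, or None when infeasible.  Exponential in the number of free
    vertices; for cross-checking the DP on small instances."""
    free = sorted(
        (n for n in refined.nodes if n not in refined.fixed_label), key=repr
    )
    best = None
    for combo in itertools.product(tumours, repeat=len(free)):
        labeling = dict(refined.fixed_label)
        labeling.update(dict(zip(free, combo)))
        mu = 0
        ok = True
        migrations = []
        for child, par in refined.parent.items():
            a, b = labeling[par], labeling[child]
            if a == b:
                continue
            if b == primary or (model == "primary_only" and a != primary):
                ok = False
                break
            mu += 1
            migrations.append((a, b))
        if not ok:
            continue
        if model == "single_source" and not _single_source_ok(migrations):
            continue
        key = (mu, len(set(migrations)))
        if best is None or key < best:
            best = key
    return best
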
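"""Association networks from scan data.

Two individuals are *associated* in a scan when they are seen within 1 m of
each other — roughly one adult body length, the distance at which touch
interactions such as grooming can occur.  Association is strictly pairwise
(no gambit-of-the-group chaining).  Dyadic association strength is the
half-weight index

    HWI = x / (x + yAB + (yA + yB) / 2)

where x counts scans with both individuals observed and associated, yAB
both observed but not associated, and yA / yB only one of them observed.
The half-weight denominator corrects for the fact that not every group
member is observed in every scan.

Whether dyads associate non-randomly is tested by permuting associations
*within* each scan: a Markov chain of degree-preserving double-edge swaps
restricted to each scan's observed individuals, with the coefficient of
variation (CV) of the HWI matrix as test statistic — preferred (and
avoided) companions inflate the spread of association indices.

Community structure is extracted with Newman's leading-eigenvector
modularity method on the weighted HWI graph; Q > 0.3 conventionally marks
a useful subdivision.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .data_io import ScanTable
from .spatial import DOOR_CENTROID, distance_to_door

MODULARITY_USEFUL = 0.3


@dataclasses.dataclass
class ScanGraph:
    """One scan's observed individuals and its binary association edges."""

    scan_id: int
    observed: list[str]
    edges: set  # of (id_a, id_b) tuples with id_a < id_b


@dataclasses.dataclass
class AssociationMatrix:
    """Symmetric half-weight index matrix plus its underlying counts."""

    ids: list
    hwi: np.ndarray
    kind: str  # "affiliative_1m" or "cooccurrence_5m"
    x: np.ndarray
    y_a: np.ndarray
    y_b: np.ndarray
    y_ab: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hwi, index=self.ids, columns=self.ids)

    def binarised(self) -> np.ndarray:
        """Edge indicator: HWI > 0."""
        return (self.hwi > 0).astype(int)

    def edge_list(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.ids), k=1)
        keep = self.hwi[iu, ju] > 0
        return pd.DataFrame(
            {
                "source": [self.ids[i] for i in iu[keep]],
                "target": [self.ids[j] for j in ju[keep]],
                "weight": self.hwi[iu, ju][keep],
            }
        )


@dataclasses.dataclass
class CommunityPartition:
    assignment: pd.Series  # individual -> integer subgroup label
    q: float
    eigen_certainty: pd.Series  # |leading eigenvector| at the deciding split

    @property
    def n_communities(self) -> int:
        return self.assignment.nunique()


@dataclasses.dataclass
class PermutationTestResult:
    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    p: float
    n_perm: int
    seed: int | None


def half_weight_index(x: float, y_a: float, y_b: float, y_ab: float) -> float:
    """Half-weight association index for one dyad; NaN when never sampled."""
    if min(x, y_a, y_b, y_ab) < 0:
        raise ValueError("counts must be nonnegative")
    denom = x + y_ab + 0.5 * (y_a + y_b)
    if denom == 0:
        return float("nan")
    return x / denom


def _canon(a: str, b: str) -> tuple:
    return (a, b) if a < b else (b, a)


def per_scan_association_graphs(
    scans: ScanTable, threshold: float = 1.0, period: str = "all"
) -> list[ScanGraph]:
    """Build each scan's binary association graph from visible positions.

    A dyad is associated iff its pairwise Euclidean distance is <= the
    threshold (inclusive).
    """
    df = scans.df if period == "all" else scans.period(period).df
    df = df[df["visible"]]
    graphs = []
    for scan_id, grp in df.groupby("scan_id", sort=True):
        obs = grp["individual"].tolist()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        edges = set()
        if len(obs) > 1:
            diff = xy[:, None, :] - xy[None, :, :]
            dist = np.hypot(diff[..., 0], diff[..., 1])
            iu, ju = np.triu_indices(len(obs), k=1)
            for i, j in zip(iu[dist[iu, ju] <= threshold], ju[dist[iu, ju] <= threshold]):
                edges.add(_canon(obs[i], obs[j]))
        graphs.append(ScanGraph(int(scan_id), obs, edges))
    return graphs


def zone_graphs(
    scans: ScanTable,
    door_centroid=DOOR_CENTROID,
    radius: float = 5.0,
    period: str = "pm",
) -> list[ScanGraph]:
    """Co-occurrence graphs: everyone within ``radius`` of the door in the
    same scan is pairwise associated (complete graph on the co-present set).
    Observed individuals outside the zone still count as sampled."""
    df = scans.df if period == "all" else scans.period(period).df
    df = df[df["visible"]]
    graphs = []
    for scan_id, grp in df.groupby("scan_id", sort=True):
        obs = grp["individual"].tolist()
        d = distance_to_door(grp["x"].to_numpy(), grp["y"].to_numpy(), door_centroid)
        in_zone = [ind for ind, dist in zip(obs, d) if dist <= radius]
        edges = {
            _canon(a, b) for k, a in enumerate(in_zone) for b in in_zone[k + 1 :]
        }
        graphs.append(ScanGraph(int(scan_id), obs, edges))
    return graphs


def association_matrix_from_graphs(
    graphs: list[ScanGraph], ids, kind: str
) -> AssociationMatrix:
    """Accumulate HWI counts over scans.

    A scan is a sample for dyad (A, B) whenever at least one of the two is
    observed in it; dyads never sampled get HWI = NaN.
    """
    ids = list(ids)
    index = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    x = np.zeros((n, n))
    n_obs = np.zeros(n)  # scans each individual observed
    n_both = np.zeros((n, n))  # scans both observed
    for g in graphs:
        present = [index[i] for i in g.observed if i in index]
        n_obs[present] += 1
        arr = np.array(present, dtype=int)
        if len(arr) > 1:
            n_both[np.ix_(arr, arr)] += 1
        for a, b in g.edges:
            if a in index and b in index:
                ia, ib = index[a], index[b]
                x[ia, ib] += 1
                x[ib, ia] += 1
    np.fill_diagonal(n_both, 0)
    y_a = n_obs[:, None] - n_both
    y_b = n_obs[None, :] - n_both
    y_ab = n_both - x
    denom = x + y_ab + 0.5 * (y_a + y_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        hwi = np.where(denom > 0, x / np.where(denom > 0, denom, 1), np.nan)
    np.fill_diagonal(hwi, 0.0)
    return AssociationMatrix(ids, hwi, kind, x, y_a, y_b, y_ab)


def affiliative_network(
    scans: ScanTable, ids, threshold: float = 1.0, period: str = "all"
) -> AssociationMatrix:
    """1-m proximity HWI network over the full observation set."""
    graphs = per_scan_association_graphs(scans, threshold, period)
    return association_matrix_from_graphs(graphs, ids, "affiliative_1m")


def cooccurrence_network(
    scans: ScanTable,
    ids,
    door_centroid=DOOR_CENTROID,
    radius: float = 5.0,
    period: str = "pm",
) -> AssociationMatrix:
    """5-m food-patch co-occurrence HWI network (afternoon scans)."""
    graphs = zone_graphs(scans, door_centroid, radius, period)
    return association_matrix_from_graphs(graphs, ids, "cooccurrence_5m")


def affiliative_network_excluding_zone(
    scans: ScanTable,
    ids,
    door_centroid=DOOR_CENTROID,
    radius: float = 5.0,
    threshold: float = 1.0,
    period: str = "all",
) -> AssociationMatrix:
    """1-m network discarding associations where both members sit within
    ``radius`` of the feeding-zone door in that scan."""
    df = scans.df if period == "all" else scans.period(period).df
    vis = df[df["visible"]]
    in_zone_lookup = {}
    d = distance_to_door(vis["x"].to_numpy(), vis["y"].to_numpy(), door_centroid)
    for (sid, ind), dist in zip(vis[["scan_id", "individual"]].itertuples(index=False), d):
        in_zone_lookup[(int(sid), ind)] = dist <= radius
    graphs = per_scan_association_graphs(scans, threshold, period)
    for g in graphs:
        g.edges = {
            (a, b)
            for a, b in g.edges
            if not (
                in_zone_lookup.get((g.scan_id, a), False)
                and in_zone_lookup.get((g.scan_id, b), False)
            )
        }
    return association_matrix_from_graphs(graphs, ids, "affiliative_1m")


# ---------------------------------------------------------------------------
# Within-scan permutation test (degree-preserving double-edge swaps)
# ---------------------------------------------------------------------------


def _cv(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0:
        return float("nan")
    return float(values.std(ddof=1) / m)


def permutation_test_nonrandom_association(
    graphs: list[ScanGraph],
    ids,
    n_perm: int = 10000,
    seed: int | None = None,
    burn_in_per_edge: int = 100,
    thin_per_edge: float = 1.0,
    _check_invariants: bool = False,
) -> PermutationTestResult:
    """Test H0: no preferred or avoided companion for any dyad.

    The null keeps each scan's observed individuals, its edge count and
    every individual's within-scan number of associates fixed, and rewires
    associations by double-edge swaps inside each scan.  One long chain is
    run over all scans: ``burn_in_per_edge * E`` attempted swaps of burn-in
    (E = total edges), then ``thin_per_edge * E`` attempted swaps between
    successive null samples so samples are well mixed.  The statistic is
    the CV of the HWI matrix; right-tailed p with the observed value
    counted once.
    """
    ids = list(ids)
    index = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)

    # Static denominators: swaps never change who is observed.
    base = association_matrix_from_graphs(graphs, ids, "affiliative_1m")
    n_obs_pair = base.x + base.y_ab + 0.5 * (base.y_a + base.y_b)
    iu, ju = np.triu_indices(n, k=1)
    sampled = n_obs_pair[iu, ju] > 0
    di, dj = iu[sampled], ju[sampled]
    denom = n_obs_pair[di, dj]

    x = base.x.copy()
    observed_cv = _cv(x[di, dj] / denom)

    # Mutable per-scan edge structures (index space).
    scan_edges: list[list] = []
    scan_sets: list[set] = []
    for g in graphs:
        edges = [
            (index[a], index[b]) for a, b in g.edges if a in index and b in index
        ]
        scan_edges.append(edges)
        scan_sets.append({(min(a, b), max(a, b)) for a, b in edges})
    swappable = [k for k, e in enumerate(scan_edges) if len(e) >= 2]
    total_edges = sum(len(e) for e in scan_edges)
    if not swappable or np.isnan(observed_cv):
        warnings.warn("no permutable association structure; p reported as 1")
        return PermutationTestResult(
            "CV of association indices", observed_cv, float("nan"), float("nan"),
            1.0, n_perm, seed,
        )

    rng = np.random.default_rng(seed)
    # Scans picked proportionally to their edge count.
    pick_pool = np.concatenate(
        [np.full(len(scan_edges[k]), k) for k in swappable]
    )

    def attempt_swaps(count: int) -> None:
        scans_chosen = pick_pool[rng.integers(0, len(pick_pool), size=count)]
        coins = rng.random(count)
        for s, coin in zip(scans_chosen, coins):
            edges = scan_edges[s]
            eset = scan_sets[s]
            ne = len(edges)
            e1 = int(rng.integers(0, ne))
            e2 = int(rng.integers(0, ne))
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if coin < 0.5:
                b, a = a, b  # randomise which endpoints pair up
            if a == d or c == b:
                continue
            new1 = (a, d) if a < d else (d, a)
            new2 = (c, b) if c < b else (b, c)
            if new1 in eset or new2 in eset:
                continue
            old1 = (a, b) if a < b else (b, a)
            old2 = (c, d) if c < d else (d, c)
            eset.discard(old1)
            eset.discard(old2)
            eset.add(new1)
            eset.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            x[old1] -= 1
            x[old1[::-1]] -= 1
            x[old2] -= 1
            x[old2[::-1]] -= 1
            x[new1] += 1
            x[new1[::-1]] += 1
            x[new2] += 1
            x[new2[::-1]] += 1

    if _check_invariants:
        ref_degrees = [
            dict(zip(*np.unique(np.array(list(e) or [(0, 0)]).ravel(), return_counts=True)))
            if e else {} for e in scan_edges
        ]
        ref_counts = [len(e) for e in scan_edges]

    attempt_swaps(burn_in_per_edge * total_edges)
    thin = max(1, int(round(thin_per_edge * total_edges)))
    null = np.empty(n_perm)
    for t in range(n_perm):
        attempt_swaps(thin)
        null[t] = _cv(x[di, dj] / denom)
        if _check_invariants:
            for k, edges in enumerate(scan_edges):
                assert len(edges) == ref_counts[k]
                deg = dict(
                    zip(*np.unique(np.array(list(edges) or [(0, 0)]).ravel(), return_counts=True))
                ) if edges else {}
                assert deg == ref_degrees[k], f"degree sequence changed in scan {k}"
    p = (np.sum(null >= observed_cv) + 1) / (n_perm + 1)
    return PermutationTestResult(
        "CV of association indices",
        observed_cv,
        float(null.mean()),
        float(null.std(ddof=1)),
        float(p),
        n_perm,
        seed,
    )


# ---------------------------------------------------------------------------
# Newman leading-eigenvector modularity
# ---------------------------------------------------------------------------


def modularity_q(weights: np.ndarray, labels: np.ndarray) -> float:
    """Weighted modularity Q = (1/2m) sum_ij (w_ij - k_i k_j / 2m) d(c_i,c_j)."""
    w = np.asarray(weights, dtype=float)
    labels = np.asarray(labels)
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("empty network: no edge weight")
    same = labels[:, None] == labels[None, :]
    b = w - np.outer(k, k) / two_m
    return float((b * same).sum() / two_m)


def _fine_tune(s: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Kernighan-Lin refinement of a bisection: repeated passes in which
    every node is moved once (greedily, even through downhill steps) and
    the best intermediate state is kept."""
    diag = np.diag(bg)
    current = float(s @ bg @ s)
    for _ in range(20):
        cur = s.copy()
        moved = np.zeros(len(s), dtype=bool)
        best_val, best_s = current, s.copy()
        val = current
        for _ in range(len(s)):
            bs = bg @ cur
            gains = -4.0 * cur * bs + 4.0 * diag
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            val += gains[i]
            cur[i] = -cur[i]
            moved[i] = True
            if val > best_val + 1e-12:
                best_val, best_s = val, cur.copy()
        if best_val > current + 1e-12:
            s, current = best_s, best_val
        else:
            break
    return s


def _refine_partition(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Greedy node-move refinement of a whole partition: each pass moves
    single nodes to whichever community (existing or new) most increases
    Q, until no improving move remains.  Recovers optima that do not nest
    inside the recursive bisections."""
    labels = labels.copy()
    k = w.sum(axis=1)
    two_m = k.sum()
    for _ in range(100):
        improved = False
        for i in range(len(labels)):
            current = labels[i]
            options = list(np.unique(labels)) + [labels.max() + 1]
            # gain of moving i from its community to community c:
            # (sum_j-in-c w_ij - k_i * K_c / 2m) evaluated without i
            best_c, best_gain = current, 0.0
            others = labels.copy()
            others[i] = -1
            for c in options:
                if c == current:
                    continue
                in_c = others == c
                in_cur = others == current
                gain = (
                    w[i, in_c].sum() - k[i] * k[in_c].sum() / two_m
                    - (w[i, in_cur].sum() - k[i] * k[in_cur].sum() / two_m)
                )
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            if best_c != current:
                labels[i] = best_c
                improved = True
        if not improved:
            break
    # relabel compactly in order of first appearance
    _, compact = np.unique(labels, return_inverse=True)
    return compact


def newman_communities(
    assoc: AssociationMatrix, tol: float = 1e-9, n_restarts: int = 8
) -> CommunityPartition:
    """Recursive leading-eigenvector bisection of the weighted HWI graph.

    Each community's generalized modularity matrix is diagonalised; the
    sign pattern of the leading eigenvector proposes a bisection, refined
    by Kernighan-Lin node moves (plus a few deterministic random restarts
    so small graphs are not trapped by the greedy split), and accepted
    only if it increases Q.  Per-node assignment certainty is the absolute
    eigenvector loading at the split that fixed the node's final community
    (0 for nodes never split).
    """
    w = np.nan_to_num(np.asarray(assoc.hwi, dtype=float))
    n = len(assoc.ids)
    k = w.sum(axis=1)
    two_m = k.sum()
    if n == 0 or two_m == 0:
        raise ValueError("empty network")
    b = w - np.outer(k, k) / two_m

    labels = np.zeros(n, dtype=int)
    certainty = np.zeros(n)
    final: list[np.ndarray] = []
    stack = [np.arange(n)]
    restart_rng = np.random.default_rng(0)  # deterministic refinement only
    while stack:
        g = stack.pop()
        if len(g) < 2:
            final.append(g)
            continue
        bg = b[np.ix_(g, g)]
        bg = bg - np.diag(bg.sum(axis=1))
        evals, evecs = np.linalg.eigh(bg)
        v = evecs[:, -1]
        candidates = [np.where(v >= 0, 1.0, -1.0)]
        if evals[-1] > tol:
            candidates += [
                restart_rng.choice([-1.0, 1.0], size=len(g))
                for _ in range(n_restarts)
            ]
        s, best = None, -np.inf
        for cand in candidates:
            refined = _fine_tune(cand.copy(), bg)
            val = refined @ bg @ refined
            if val > best:
                s, best = refined, val
        delta_q = best / (2.0 * two_m)
        if delta_q <= tol or np.all(s > 0) or np.all(s < 0):
            final.append(g)
            continue
        certainty[g] = np.abs(v)
        stack.append(g[s > 0])
        stack.append(g[s < 0])

    for lab, g in enumerate(sorted(final, key=lambda grp: int(grp.min()))):
        labels[g] = lab
    labels = _refine_partition(w, labels)
    q = modularity_q(w, labels)
    # Greedy node-move search from random partitions can escape optima the
    # nested bisections cannot reach; keep whichever scores best.
    for _ in range(n_restarts):
        start = restart_rng.integers(0, max(2, n // 3 + 1), size=n)
        cand = _refine_partition(w, start)
        q_cand = modularity_q(w, cand)
        if q_cand > q + 1e-12:
            labels, q = cand, q_cand
    idx = pd.Index(assoc.ids, name="individual")
    return CommunityPartition(
        pd.Series(labels, index=idx, name="subgroup"),
        q,
        pd.Series(certainty, index=idx, name="certainty"),
    )
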
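"""Dominance hierarchy: win matrix, David's score (MDS) and linearity (h').

The hierarchy is built from dyadic agonistic interactions with a clear
outcome.  Polyadic interactions (more than two participants) and
bidirectional/unclear bouts are discarded.  From the win matrix we compute:

* the dyadic dominance index D_ij = P_ij - (P_ij - 1/2)/(n_ij + 1), a
  chance-corrected win proportion that shrinks small samples toward 1/2;
* the modified David's score MDS_i = w_i + w2_i - l_i - l2_i on D, a
  cardinal dominance index that always sums to zero over the group;
* Landau's linearity index h and de Vries' h', which corrects h for
  unknown relationships, with a randomization test of linearity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class WinMatrix:
    """Directed dyadic win counts.

    ``s[i, j]`` is the number of decided dyadic interactions won by
    individual ``ids[i]`` over ``ids[j]``; ``n = s + s.T`` counts
    interactions per dyad.
    """

    ids: list
    s: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (len(self.ids), len(self.ids)):
            raise ValueError("win matrix shape does not match ids")
        if (self.s < 0).any():
            raise ValueError("negative win counts")
        if np.diag(self.s).any():
            raise ValueError("nonzero diagonal in win matrix")

    @property
    def n(self) -> np.ndarray:
        return self.s + self.s.T


@dataclasses.dataclass
class DominanceResult:
    mds: pd.Series
    h_prime: float
    p_linearity: float
    n_randomizations: int
    seed: int | None = None


def build_win_matrix(records: pd.DataFrame, ids) -> tuple[WinMatrix, dict]:
    """Count decided dyadic wins between included individuals.

    Filtering rules, applied in order:

    1. interactions with more than two participants are discarded;
    2. interactions without a clear outcome are discarded;
    3. interactions involving anyone outside ``ids`` are discarded;
    4. when several records share (timestamp, actor, receiver) — a behaviour
       sequence within one bout — only the final record (the behaviour that
       caused submission) is counted.

    Returns the matrix plus a bookkeeping report of discarded counts.
    """
    ids = list(ids)
    index = {ind: k for k, ind in enumerate(ids)}
    df = records.copy()

    polyadic = df["n_participants"] > 2
    unclear = ~polyadic & ~df["clear_outcome"]
    outside = (
        ~polyadic
        & ~unclear
        & (~df["actor"].isin(index) | ~df["receiver"].isin(index))
    )
    kept = df[~polyadic & ~unclear & ~outside]
    n_before_dedup = len(kept)
    kept = kept.sort_index().drop_duplicates(
        subset=["timestamp", "actor", "receiver"], keep="last"
    )

    s = np.zeros((len(ids), len(ids)))
    for actor, receiver in kept[["actor", "receiver"]].itertuples(index=False):
        s[index[actor], index[receiver]] += 1

    report = {
        "n_records": int(len(df)),
        "n_polyadic_discarded": int(polyadic.sum()),
        "n_unclear_discarded": int(unclear.sum()),
        "n_outside_roster_discarded": int(outside.sum()),
        "n_sequence_collapsed": int(n_before_dedup - len(kept)),
        "n_counted": int(len(kept)),
    }
    return WinMatrix(ids, s), report


def dyadic_dominance_index(win: WinMatrix) -> np.ndarray:
    """Chance-corrected dyadic dominance index D.

    D_ij = P_ij - (P_ij - 1/2)/(n_ij + 1) with P_ij = s_ij / n_ij; dyads
    that never interacted get D_ij = D_ji = 0.  For interacting dyads
    D_ij + D_ji = 1.
    """
    n = win.n
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, win.s / np.where(n > 0, n, 1), 0.0)
        d = p - (p - 0.5) / (n + 1)
    d = np.where(n > 0, d, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def david_score(d: np.ndarray, ids=None) -> pd.Series:
    """Modified David's score from a dyadic dominance index matrix.

    DS_i = w_i + w2_i - l_i - l2_i with w_i = sum_j D_ij,
    w2_i = sum_j D_ij w_j, l_i = sum_j D_ji, l2_i = sum_j D_ji l_j.
    Scores sum to zero.
    """
    d = np.asarray(d, dtype=float)
    w = d.sum(axis=1)
    l = d.sum(axis=0)
    w2 = d @ w
    l2 = d.T @ l
    ds = w + w2 - l - l2
    index = list(ids) if ids is not None else list(range(len(ds)))
    return pd.Series(ds, index=index, name="MDS")


def mds(win: WinMatrix) -> pd.Series:
    """Convenience: modified David's score straight from a win matrix.

    Individuals with no interactions at all get a score of NaN (they carry
    no dominance information and are dropped from downstream models).
    """
    scores = david_score(dyadic_dominance_index(win), win.ids)
    isolated = win.n.sum(axis=1) == 0
    scores[isolated] = np.nan
    return scores


def _relationship_vectors(win: WinMatrix):
    """Decompose dyads into known wins, ties and unknowns.

    Returns (v_fixed, unknown_pairs) where v_fixed[i] counts 1 per dyad i
    clearly dominates and 0.5 per observed tie, and unknown_pairs lists the
    (i, j) index pairs with no interactions.
    """
    s, n = win.s, win.n
    nn = len(win.ids)
    iu, ju = np.triu_indices(nn, k=1)
    wins_i = s[iu, ju] > s[ju, iu]
    wins_j = s[ju, iu] > s[iu, ju]
    tied = (n[iu, ju] > 0) & ~wins_i & ~wins_j
    unknown = n[iu, ju] == 0

    v = np.zeros(nn)
    np.add.at(v, iu[wins_i], 1.0)
    np.add.at(v, ju[wins_j], 1.0)
    np.add.at(v, iu[tied], 0.5)
    np.add.at(v, ju[tied], 0.5)
    unknown_pairs = np.column_stack([iu[unknown], ju[unknown]])
    return v, unknown_pairs


def landau_h(v: np.ndarray) -> float:
    """Landau's linearity index from the dominance vector V.

    h = 12/(N^3 - N) * sum_i (V_i - (N-1)/2)^2, where V_i is the number of
    individuals i dominates (ties and unknowns contributing 1/2 each).
    """
    n = len(v)
    if n < 3:
        raise ValueError("linearity undefined for fewer than 3 individuals")
    return float(12.0 / (n**3 - n) * np.sum((v - (n - 1) / 2.0) ** 2))


def linearity_h_prime(
    win: WinMatrix, n_randomizations: int = 10000, seed: int | None = None
) -> tuple[float, float]:
    """de Vries' improved linearity index h' with a randomization test.

    h' corrects Landau's h for unknown relationships: with unknown dyads
    counted as half-wins, h' = h + 6u/(N^3 - N) where u is the number of
    unknown dyads — the expected h when each unknown relationship is
    resolved by a fair coin.  Observed ties stay fixed at 1/2.

    The p-value follows the two-step randomization: at each iteration the
    observed matrix's unknown dyads are resolved at random (giving h_obs)
    and compared against the h of a fully random tournament of the same
    size; p is the right-tailed proportion of iterations where the random
    tournament is at least as linear, with the observed comparison counted
    once (p >= 1/(R+1)).
    """
    nn = len(win.ids)
    if nn < 3:
        raise ValueError("need at least 3 individuals")
    v_fixed, unknown = _relationship_vectors(win)
    u = len(unknown)

    v_expected = v_fixed.copy()
    if u:
        np.add.at(v_expected, unknown[:, 0], 0.5)
        np.add.at(v_expected, unknown[:, 1], 0.5)
    h_ties = landau_h(v_expected)
    h_prime = h_ties + 6.0 * u / (nn**3 - nn)

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(nn, k=1)
    count = 0
    for _ in range(n_randomizations):
        v_obs = v_fixed.copy()
        if u:
            flips = rng.random(u) < 0.5
            np.add.at(v_obs, np.where(flips, unknown[:, 0], unknown[:, 1]), 1.0)
        h_obs = landau_h(v_obs)

        v_rand = np.zeros(nn)
        direction = rng.random(len(iu)) < 0.5
        np.add.at(v_rand, np.where(direction, iu, ju), 1.0)
        if landau_h(v_rand) >= h_obs:
            count += 1
    p = (count + 1) / (n_randomizations + 1)
    return float(h_prime), float(p)


def dominance_analysis(
    records: pd.DataFrame, ids, n_randomizations: int = 10000, seed: int | None = None
) -> tuple[DominanceResult, dict]:
    """Full hierarchy analysis: win matrix -> MDS -> linearity."""
    win, report = build_win_matrix(records, ids)
    scores = mds(win)
    h_prime, p = linearity_h_prime(win, n_randomizations, seed)
    return DominanceResult(scores, h_prime, p, n_randomizations, seed), report
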
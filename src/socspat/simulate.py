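"""Synthetic scan-sampling data with the structure the analysis assumes.

The generator emulates a provisioned, semi-free group observed in front of
a feeding zone: ~39 adults (21 males, 18 females, ages 5-26) scanned every
15 minutes over 09:00-12:00 and 15:00-18:00 (26 scans/day), with higher
afternoon attendance, a feeding-zone door whose attraction increases with
a latent dominance scale, subgroup- and kin-assortative 1-m associations,
and agonistic outcomes driven by the same latent scale.  The latent state
(dominance scores, planted subgroups) is returned as ground truth for
recovery tests.

Placement model: each planted subgroup (a union of whole matrilines) gets
a per-scan anchor point whose expected distance to the door decreases
with the subgroup's mean latent dominance (plus a centred per-subgroup
distance bias and a persistent home bearing, both constant over the
study); members sit within ~1 m of their anchor with a probability set by
``subgroup_cohesion``, and otherwise at an independently drawn distance
driven by their own dominance.  Positions are truncated-normal around
these anchors, clipped to the 30 x 30 m area and digitised to 1-m cell
centres like the field records.  Out-of-sight individuals are Bernoulli
non-attenders recorded as visible = False rows.

``subgroup_cohesion`` and ``kin_association_boost`` are odds-style
multipliers mapped to anchor probabilities p = 1 - 1/value, so a value of
1 is exactly neutral (no planted association structure).
"""

from __future__ import annotations

import dataclasses
import json
from datetime import date as ddate, datetime, time as dtime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ScanTable, write_agonistic, write_individuals, write_scan_table
from .spatial import DOOR_CENTROID

STUDY_START = ddate(2012, 4, 2)

AM_TIMES = [dtime(9 + (15 * j) // 60, (15 * j) % 60) for j in range(13)]
PM_TIMES = [dtime(15 + (15 * j) // 60, (15 * j) % 60) for j in range(13)]


def sampling_schedule() -> list[tuple[str, dtime]]:
    """The daily scan schedule: 09:00-12:00 and 15:00-18:00 at 15-min
    frequency, endpoints included (13 + 13 = 26 scans/day)."""
    return [("am", t) for t in AM_TIMES] + [("pm", t) for t in PM_TIMES]


def total_observation_hours(n_scans: int, minutes_per_scan: float = 15.0) -> float:
    """Observation effort implied by a scan count at a given frequency."""
    return n_scans * minutes_per_scan / 60.0


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults mirror the field study."""

    n_individuals: int = 39
    n_males: int = 21
    n_matrilines: int = 9
    age_range: tuple = (5.0, 26.0)
    n_juveniles: int = 0  # optional under-5 roster entries (never observed)
    n_days: int = 24
    attendance_prob_am: float = 0.16
    attendance_prob_pm: float = 0.30
    #: logit-scale shift in attendance per SD of the subgroup's mean latent
    #: dominance: dominant subgroups frequent the competition area while
    #: subordinate ones stay in the forest (out of sight) more often
    attendance_dominance_slope: float = 0.4
    n_subgroups: int = 8
    #: metres of expected anchor-to-door distance lost per SD of the
    #: subgroup's mean latent dominance
    door_attraction_slope: float = 6.0
    #: same, for an individual's own (non-anchored) placements; weaker than
    #: the subgroup-level pull so that spatial structure is primarily a
    #: subgroup property
    individual_attraction_slope: float = 1.0
    subgroup_cohesion: float = 5.0  # odds multiplier; 1 = no cohesion
    kin_association_boost: float = 1.5  # odds multiplier; 1 = no kin effect
    hierarchy_steepness: float = 1.5  # logistic slope per SD dominance gap
    interactions_per_day: int = 90
    polyadic_rate: float = 0.04
    unclear_rate: float = 0.04
    #: latent dominance = sex_effect * (male) + age_effect * age + noise
    sex_effect: float = 2.0
    age_effect: float = 0.1
    dominance_noise_sd: float = 0.6
    base_distance: float = 12.0  # expected door distance at mean dominance
    individual_distance_sd: float = 3.0
    anchor_distance_sd: float = 2.0
    subgroup_spatial_sd: float = 4.0  # per-subgroup constant distance bias
    within_anchor_sd: float = 0.45  # spread around an anchor (m)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 3:
            raise ValueError("need at least 3 individuals")
        if not 0 <= self.n_males <= self.n_individuals:
            raise ValueError("infeasible sex ratio")
        for p in (self.attendance_prob_am, self.attendance_prob_pm):
            if not 0 <= p <= 1:
                raise ValueError("attendance probabilities must be in [0, 1]")
        if min(self.subgroup_cohesion, self.kin_association_boost) < 1:
            raise ValueError("cohesion/kin multipliers must be >= 1")
        if self.n_subgroups > self.n_matrilines:
            raise ValueError("need at least one matriline per subgroup")
        if self.n_matrilines > self.n_individuals:
            raise ValueError("more matrilines than individuals")


@dataclasses.dataclass
class LatentState:
    """Ground truth behind a simulated dataset."""

    dominance: pd.Series  # standardized latent dominance per individual
    subgroup: pd.Series  # planted subgroup label per individual
    matriline: pd.Series


def _odds_to_prob(multiplier: float) -> float:
    return 1.0 - 1.0 / multiplier


def generate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, LatentState]:
    """Sexes, ages, matrilines, latent dominance and planted subgroups.

    Latent dominance is sex_effect*(male) + age_effect*age + noise and is
    reported standardized.  Planted subgroups are unions of whole
    matrilines (kin ties never cross a subgroup boundary), so associations
    are kin-assortative within subgroups as observed in provisioned
    mandrill groups.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_individuals
    ids = [f"ind{k:02d}" for k in range(1, n + 1)]
    sex = np.array(["M"] * config.n_males + ["F"] * (n - config.n_males))
    rng.shuffle(sex)
    lo, hi = config.age_range
    age = np.round(rng.uniform(lo, hi, size=n), 1)
    # every matriline is represented at least once; the rest is random
    mat_idx = np.concatenate(
        [
            np.arange(config.n_matrilines),
            rng.integers(0, config.n_matrilines, size=n - config.n_matrilines),
        ]
    )
    rng.shuffle(mat_idx)
    matriline = np.array([f"mat{k + 1}" for k in mat_idx])

    raw = (
        config.sex_effect * (sex == "M")
        + config.age_effect * age
        + rng.normal(0, config.dominance_noise_sd, size=n)
    )
    z = (raw - raw.mean()) / raw.std()

    # Subgroups are unions of whole matrilines (kin ties never straddle a
    # subgroup boundary), allocated largest-first to balance sizes.
    subgroup = np.empty(n, dtype=int)
    mat_names, mat_counts = np.unique(matriline, return_counts=True)
    totals = np.zeros(config.n_subgroups, dtype=int)
    for mi in np.argsort(-mat_counts):
        g = int(np.argmin(totals))
        subgroup[matriline == mat_names[mi]] = g
        totals[g] += mat_counts[mi]

    birth = [
        (datetime.combine(STUDY_START, dtime()) - timedelta(days=float(a) * 365.25)).date()
        for a in age
    ]
    frames = [
        pd.DataFrame(
            {"id": ids, "sex": sex, "birth_date": birth, "age": age, "matriline": matriline}
        )
    ]
    if config.n_juveniles:
        jn = config.n_juveniles
        jids = [f"juv{k:02d}" for k in range(1, jn + 1)]
        jage = np.round(rng.uniform(0.2, 4.9, size=jn), 1)
        frames.append(
            pd.DataFrame(
                {
                    "id": jids,
                    "sex": rng.choice(["F", "M"], size=jn),
                    "birth_date": [
                        (datetime.combine(STUDY_START, dtime()) - timedelta(days=float(a) * 365.25)).date()
                        for a in jage
                    ],
                    "age": jage,
                    "matriline": [f"mat{rng.integers(1, config.n_matrilines + 1)}" for _ in range(jn)],
                }
            )
        )
    individuals = pd.concat(frames, ignore_index=True)
    idx = pd.Index(ids, name="individual")
    latent = LatentState(
        pd.Series(z, index=idx, name="dominance"),
        pd.Series(subgroup, index=idx, name="subgroup"),
        pd.Series(matriline, index=idx, name="matriline"),
    )
    return individuals, latent


def _draw_point(center_x, center_y, distance, rng, theta0=None, jitter=0.15, tries: int = 30):
    """Point at ~``distance`` from (center_x, center_y), inside the area.

    With ``theta0`` the direction is drawn around that bearing (a home
    sector); otherwise, and as fallback, uniformly at random.
    """
    for attempt in range(tries):
        if theta0 is not None and attempt < tries // 2:
            theta = theta0 + rng.normal(0, jitter)
        else:
            theta = rng.uniform(0, 2 * np.pi)
        x = center_x + distance * np.cos(theta)
        y = center_y + distance * np.sin(theta)
        if 0 <= x < 30 and 0 <= y < 30:
            return x, y
    return min(max(x, 0.0), 29.99), min(max(y, 0.0), 29.99)


def _snap(x: float, y: float) -> tuple[float, float]:
    """Digitise to the 1-m grid's cell centre, like the field maps."""
    return np.floor(min(max(x, 0.0), 29.99)) + 0.5, np.floor(min(max(y, 0.0), 29.99)) + 0.5


def generate_scans(
    individuals: pd.DataFrame,
    latent: LatentState,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ScanTable:
    """Simulate the full scan table (one row per scan x study individual)."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ids = list(latent.dominance.index)
    z = latent.dominance.to_numpy()
    sub = latent.subgroup.to_numpy()
    mats = latent.matriline.to_numpy()
    n = len(ids)
    p_anchor = _odds_to_prob(config.subgroup_cohesion)
    p_kin = _odds_to_prob(config.kin_association_boost)
    # Relative spatial preference among subgroups: centred so the group's
    # overall distance scale stays at base_distance.
    sub_bias = rng.normal(0, config.subgroup_spatial_sd, size=config.n_subgroups)
    sub_bias -= sub_bias.mean()
    # Persistent home direction per subgroup: subgroups hold distinct,
    # evenly spaced sectors of the area, so equal door distances need not
    # mean contact.
    sub_theta = rng.permutation(np.linspace(0.05, 1.65, config.n_subgroups))
    sub_mean_z = np.array(
        [z[sub == g].mean() if (sub == g).any() else 0.0 for g in range(config.n_subgroups)]
    )
    door_x, door_y = DOOR_CENTROID
    id_to_idx = {ind: k for k, ind in enumerate(ids)}

    rows = []
    scan_id = 0
    schedule = sampling_schedule()
    for day in range(config.n_days):
        date = STUDY_START + timedelta(days=day)
        for period, t in schedule:
            scan_id += 1
            p_att = config.attendance_prob_am if period == "am" else config.attendance_prob_pm
            logit = np.log(p_att / (1 - p_att)) + config.attendance_dominance_slope * sub_mean_z[sub]
            attends = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
            # Subgroup anchors for this scan
            anchors = {}
            for g in np.unique(sub[attends]):
                r = config.base_distance - config.door_attraction_slope * sub_mean_z[g]
                r += sub_bias[g] + rng.normal(0, config.anchor_distance_sd)
                anchors[g] = _draw_point(
                    door_x, door_y, max(0.5, r), rng, theta0=sub_theta[g]
                )
            placed: dict[str, tuple[float, float]] = {}
            for i in np.flatnonzero(attends):
                if rng.random() < p_anchor:
                    ax, ay = anchors[sub[i]]
                    x = ax + rng.normal(0, config.within_anchor_sd)
                    y = ay + rng.normal(0, config.within_anchor_sd)
                else:
                    kin_here = [j for j in placed if mats[id_to_idx[j]] == mats[i]]
                    if kin_here and rng.random() < p_kin:
                        kx, ky = placed[kin_here[0]]
                        x = kx + rng.normal(0, config.within_anchor_sd)
                        y = ky + rng.normal(0, config.within_anchor_sd)
                    else:
                        r = config.base_distance - config.individual_attraction_slope * z[i]
                        r += rng.normal(0, config.individual_distance_sd)
                        x, y = _draw_point(door_x, door_y, max(0.5, r), rng)
                x, y = _snap(x, y)
                placed[ids[i]] = (x, y)
            for i, ind in enumerate(ids):
                if ind in placed:
                    px, py = placed[ind]
                    rows.append((scan_id, date, t, ind, px, py, True))
                else:
                    rows.append((scan_id, date, t, ind, np.nan, np.nan, False))
    df = pd.DataFrame(
        rows, columns=["scan_id", "date", "time", "individual", "x", "y", "visible"]
    )
    return ScanTable(df)


def generate_agonistic(
    individuals: pd.DataFrame,
    latent: LatentState,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the ad libitum agonistic log.

    Winner of a dyadic bout follows a logistic in the latent dominance gap.
    Polyadic (3-participant) and unclear-outcome records are injected at
    the configured rates as *extra* rows so the downstream filters can be
    audited; the returned report counts them.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    ids = list(latent.dominance.index)
    z = latent.dominance.to_numpy()
    n = len(ids)
    windows = [(dtime(9, 0), 3), (dtime(15, 0), 3)]

    rows = []
    n_polyadic = n_unclear = 0
    counter = 0
    for day in range(config.n_days):
        date = STUDY_START + timedelta(days=day)
        for _ in range(config.interactions_per_day):
            i, j = rng.choice(n, size=2, replace=False)
            gap = config.hierarchy_steepness * (z[i] - z[j])
            p_win = 1.0 / (1.0 + np.exp(-gap))
            winner, loser = (i, j) if rng.random() < p_win else (j, i)
            start, hours = windows[int(rng.integers(0, 2))]
            seconds = int(rng.integers(0, hours * 3600))
            ts = datetime.combine(date, start) + timedelta(
                seconds=seconds, microseconds=counter % 1000000
            )
            counter += 1
            u = rng.random()
            if u < config.polyadic_rate:
                rows.append((ts, ids[winner], ids[loser], "chase", 3, True))
                n_polyadic += 1
            elif u < config.polyadic_rate + config.unclear_rate:
                rows.append((ts, ids[winner], ids[loser], "threat", 2, False))
                n_unclear += 1
            else:
                rows.append((ts, ids[winner], ids[loser], "supplant", 2, True))
    df = pd.DataFrame(
        rows,
        columns=["timestamp", "actor", "receiver", "behavior", "n_participants", "clear_outcome"],
    )
    report = {
        "n_records": len(df),
        "n_polyadic_injected": n_polyadic,
        "n_unclear_injected": n_unclear,
        "n_dyadic_clear": len(df) - n_polyadic - n_unclear,
    }
    return df, report


#: Default planted effect sizes for dyadic-recovery simulations: kin dyads
#: and same-sex dyads associate more, on a unit-noise scale.
DEFAULT_DYADIC_EFFECTS = {"kinship": 0.5, "sex_same": 0.3}


def generate_dyadic_outcome(
    predictors: dict,
    betas: dict,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Symmetric dyadic response with planted linear effects, for testing
    matrix-regression recovery: Y = sum_k beta_k X_k + symmetric noise."""
    rng = np.random.default_rng() if rng is None else rng
    mats = {k: np.asarray(v, dtype=float) for k, v in predictors.items()}
    n = next(iter(mats.values())).shape[0]
    y = np.zeros((n, n))
    for k, b in betas.items():
        y += b * mats[k]
    noise = rng.normal(0, noise_sd, size=(n, n))
    y += np.triu(noise, 1) + np.triu(noise, 1).T
    np.fill_diagonal(y, 0.0)
    return y


@dataclasses.dataclass
class SimulatedDataset:
    individuals: pd.DataFrame
    scans: ScanTable
    agonistic: pd.DataFrame
    latent: LatentState
    report: dict


def generate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Full deterministic dataset from one config/seed."""
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    individuals, latent = generate_population(config, rng)
    scans = generate_scans(individuals, latent, config, rng)
    agonistic, report = generate_agonistic(individuals, latent, config, rng)
    return SimulatedDataset(individuals, scans, agonistic, latent, report)


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write scans.csv, agonistic.csv, individuals.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_scan_table(dataset.scans, outdir / "scans.csv")
    write_agonistic(dataset.agonistic, outdir / "agonistic.csv")
    write_individuals(dataset.individuals, outdir / "individuals.csv")
    truth = {
        "dominance": dataset.latent.dominance.to_dict(),
        "subgroup": {k: int(v) for k, v in dataset.latent.subgroup.items()},
        "matriline": dataset.latent.matriline.to_dict(),
        "agonistic_report": dataset.report,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
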
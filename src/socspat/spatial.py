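"""Per-individual spatial frequencies relative to the feeding-zone door.

Two measures summarise where an individual sits during feeding competition:

* ``F10M`` — the *relative* frequency of afternoon scans in which the
  individual was observed within 10 m of the door, i.e. a proportion of the
  scans in which it was observed at all.
* ``F20M`` — the *absolute* count of afternoon scans in which it was either
  observed more than 20 m from the door or out of sight (in the forest).
  Out-of-sight scans count because an individual that left the area is, a
  fortiori, far from the food patch.

Observations between 10 and 20 m contribute to neither measure: the two
buffers deliberately contrast proximity with distance.  ``SRF10M`` is the
square-root transform of F10M used by downstream regressions to stabilise
its variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import ScanTable

#: Centre of the feeding-zone door: the door polygon spans x in [5, 6],
#: y in [3, 4] on the observation map.
DOOR_CENTROID = (5.5, 3.5)
R_NEAR = 10.0
R_FAR = 20.0


def distance_to_door(x, y, door_centroid=DOOR_CENTROID):
    """Euclidean distance (m) from point(s) to the door centroid.

    NaN coordinates mark out-of-sight records and propagate to NaN: an
    unobserved individual has no distance, never a number.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - door_centroid[0], y - door_centroid[1]
    return np.hypot(dx, dy)


def compute_spatial_frequencies(
    scans: ScanTable,
    door_centroid=DOOR_CENTROID,
    r_near: float = R_NEAR,
    r_far: float = R_FAR,
    period: str = "pm",
    ids=None,
) -> pd.DataFrame:
    """Compute F10M / SRF10M / F20M per individual from one observation block.

    Parameters
    ----------
    scans : ScanTable
        Full scan table; rows are filtered to ``period`` here.
    period : {"pm", "am", "all"}
        Observation block to use.  Afternoon is the default: food was
        delivered reliably at the end of the afternoon block, so that is
        when feeding competition is expected.
    ids : list of str, optional
        Individuals to report (defaults to everyone in the table).  An
        individual never observed in the period gets F10M = NaN (flagged in
        ``f10m_defined``) while F20M still counts its out-of-sight scans.

    Returns
    -------
    pandas.DataFrame indexed by individual with columns
    ``n_scans_observed_pm, F10M, SRF10M, F20M, f10m_defined``.

    Notes
    -----
    Boundary conventions: "within 10 m" is inclusive (d <= r_near) and
    "over 20 m" exclusive (d > r_far).
    """
    df = scans.df if period == "all" else scans.period(period).df
    if ids is None:
        ids = sorted(df["individual"].unique())
    ids = list(ids)

    d = distance_to_door(df["x"].to_numpy(), df["y"].to_numpy(), door_centroid)
    visible = df["visible"].to_numpy()
    frame = pd.DataFrame(
        {
            "individual": df["individual"].to_numpy(),
            "observed": visible,
            "near": visible & (d <= r_near),
            "far": visible & (d > r_far),
            "out_of_sight": ~visible,
        }
    )
    agg = frame.groupby("individual").sum().reindex(ids, fill_value=0)

    n_obs = agg["observed"].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        f10m = agg["near"] / n_obs.where(n_obs > 0)
    out = pd.DataFrame(index=pd.Index(ids, name="individual"))
    out["n_scans_observed_pm"] = n_obs
    out["F10M"] = f10m
    out["SRF10M"] = np.sqrt(f10m)
    out["F20M"] = (agg["far"] + agg["out_of_sight"]).astype(int)
    out["f10m_defined"] = n_obs > 0
    return out
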
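"""End-to-end analysis: spatial position vs dominance and affiliation.

Runs the three hypothesis analyses from the three input tables:

* **H1** — does dominance explain proximity to the food patch?  One-tailed
  permutation Pearson correlations of SRF10M (positive) and F20M
  (negative) with the modified David's score (MDS).
* **H2** — do affiliative subgroups explain it too?  Variance partition of
  SRF10M and F20M on MDS plus subgroup dummies, with semipartial r² per
  block and permutation p-values.
* **H3** — are individuals co-occurring at the patch close or distant in
  rank?  MRQAP-DSP of the 5-m co-occurrence HWI on dominance distance,
  controlling kinship, age distance and sex similarity; a Mantel test
  against the zone-excluded affiliative network; and the percentage of
  zone dyads also associated elsewhere.

Every stage logs record counts after its filters so the descriptive
numbers of a run are auditable, and every p-value is reported with its
n_perm and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, dominance as dom, inference, networks, spatial
from .data_io import ScanTable

logger = logging.getLogger("socspat")


@dataclasses.dataclass
class AnalysisConfig:
    """Every analysis choice as a named key; defaults follow the study."""

    door_x: float = 5.5
    door_y: float = 3.5
    r_near: float = 10.0
    r_far: float = 20.0
    zone_radius: float = 5.0
    association_threshold: float = 1.0
    spatial_period: str = "pm"
    association_period: str = "all"
    f10m_denominator: str = "period"  # or "all": observed scans in any period
    min_age: float = 5.0
    subadult_max_age: float = 7.0
    n_perm: int = 10000
    n_randomizations: int = 10000
    cv_burn_in_per_edge: int = 100
    cv_thin_per_edge: float = 1.0
    permute_mode: str = "response"  # or "residuals" (sensitivity)
    seed: int = 0

    @property
    def door(self) -> tuple:
        return (self.door_x, self.door_y)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def overlap_percentage(zone_binary: np.ndarray, elsewhere_binary: np.ndarray):
    """Percentage of zone dyads (edges) also present in the other network.

    Both inputs are binary adjacency matrices (HWI > 0).  Returns None when
    the zone network has no dyads (the percentage is then undefined).
    """
    zone = np.asarray(zone_binary)
    other = np.asarray(elsewhere_binary)
    iu, ju = np.triu_indices(zone.shape[0], k=1)
    zone_edges = zone[iu, ju] > 0
    n_zone = int(zone_edges.sum())
    if n_zone == 0:
        return None
    shared = int((other[iu, ju][zone_edges] > 0).sum())
    return 100.0 * shared / n_zone


def _fill(hwi: np.ndarray) -> np.ndarray:
    """Never-sampled dyads (NaN HWI) enter models as 0."""
    return np.nan_to_num(np.asarray(hwi, dtype=float))


def _sub(matrix: pd.DataFrame, ids) -> pd.DataFrame:
    return matrix.loc[ids, ids]


def _hash_input(source) -> str:
    if isinstance(source, (str, Path)) and Path(source).exists():
        return hashlib.sha256(Path(source).read_bytes()).hexdigest()[:16]
    return "in-memory"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def _ptag(p: float, n_perm: int, seed: int) -> dict:
    return {"p": p, "n_perm": n_perm, "seed": seed}


def run_pipeline(
    scans,
    agonistic,
    individuals,
    config: AnalysisConfig | None = None,
    outdir=None,
) -> dict:
    """Execute filters -> spatial metrics -> dominance -> networks -> H1-H3.

    ``scans``, ``agonistic`` and ``individuals`` may be file paths or
    already-loaded objects.  Returns the report dict; with ``outdir`` the
    report and all derived tables are also written there.
    """
    cfg = AnalysisConfig() if config is None else config
    seeds = {name: (cfg.seed * 1009 + k) % 2**31 for k, name in enumerate(
        ["h_prime", "cv_test", "hier_sex", "hier_age", "affil_mrqap",
         "h1_near", "h1_far", "h2_near", "h2_far", "h3_mrqap", "h3_mantel"]
    )}
    provenance = {
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "input_hashes": {
            "scans": _hash_input(scans),
            "agonistic": _hash_input(agonistic),
            "individuals": _hash_input(individuals),
        },
    }

    stage = "load"
    try:
        if not isinstance(individuals, pd.DataFrame):
            individuals = data_io.read_individuals(individuals)
        if not isinstance(scans, ScanTable):
            scans = data_io.read_scan_table(scans, known_ids=individuals["id"])
        if not isinstance(agonistic, pd.DataFrame):
            agonistic = data_io.read_agonistic(agonistic)
        logger.info(
            "load: %d individuals, %d scans, %d agonistic records",
            len(individuals), scans.n_scans, len(agonistic),
        )

        stage = "filters"
        individuals = data_io.impute_missing_ages(individuals, cfg.subadult_max_age)
        included, filter_report = data_io.apply_study_filters(individuals, cfg.min_age)
        meta = individuals.set_index("id").loc[included].reset_index()
        logger.info("filters: %(n_included)d retained, %(n_excluded)d excluded", filter_report)

        stage = "spatial_metrics"
        freqs = spatial.compute_spatial_frequencies(
            scans, cfg.door, cfg.r_near, cfg.r_far, cfg.spatial_period, ids=included
        )
        if cfg.f10m_denominator == "all":
            all_freqs = spatial.compute_spatial_frequencies(
                scans, cfg.door, cfg.r_near, cfg.r_far, "all", ids=included
            )
            n_all = all_freqs["n_scans_observed_pm"]
            near = freqs["F10M"] * freqs["n_scans_observed_pm"]
            freqs["F10M"] = near / n_all.where(n_all > 0)
            freqs["SRF10M"] = np.sqrt(freqs["F10M"])

        stage = "dominance"
        win, dom_report = dom.build_win_matrix(agonistic, included)
        mds = dom.mds(win)
        h_prime, p_lin = dom.linearity_h_prime(
            win, cfg.n_randomizations, seeds["h_prime"]
        )
        logger.info(
            "dominance: %(n_counted)d interactions counted, "
            "%(n_polyadic_discarded)d polyadic and %(n_unclear_discarded)d unclear discarded",
            dom_report,
        )

        stage = "networks"
        affiliative = networks.affiliative_network(
            scans, included, cfg.association_threshold, cfg.association_period
        )
        graphs = networks.per_scan_association_graphs(
            scans, cfg.association_threshold, cfg.association_period
        )
        cv_test = networks.permutation_test_nonrandom_association(
            graphs, included, cfg.n_perm, seeds["cv_test"],
            cfg.cv_burn_in_per_edge, cfg.cv_thin_per_edge,
        )
        partition = networks.newman_communities(affiliative)
        cooccurrence = networks.cooccurrence_network(
            scans, included, cfg.door, cfg.zone_radius, cfg.spatial_period
        )
        excluded_zone = networks.affiliative_network_excluding_zone(
            scans, included, cfg.door, cfg.zone_radius,
            cfg.association_threshold, cfg.association_period,
        )
        logger.info(
            "networks: CV=%.4f p=%.4g; %d subgroups, Q=%.3f",
            cv_test.observed, cv_test.p, partition.n_communities, partition.q,
        )

        # Individuals entering the statistical models: defined MDS required.
        model_ids = [i for i in included if not np.isnan(mds[i])]
        n_dropped = len(included) - len(model_ids)
        if n_dropped:
            logger.info("models: dropped %d individuals with missing MDS", n_dropped)
        model_meta = meta.set_index("id").loc[model_ids].reset_index()
        mds_model = mds[model_ids]
        freqs_model = freqs.loc[model_ids]
        labels = partition.assignment[model_ids]

        stage = "hierarchy_structure"
        order = ["F", "M"]
        t_stat, t_p = inference.perm_ttest(
            mds_model.to_numpy(),
            model_meta["sex"].to_numpy(),
            alternative="less",  # first group F: males hypothesised greater
            n_perm=cfg.n_perm,
            seed=seeds["hier_sex"],
        )
        age_tests = {}
        subsets = {"all": np.ones(len(model_meta), dtype=bool)}
        subsets.update({s: (model_meta["sex"] == s).to_numpy() for s in order})
        for name, mask in subsets.items():
            r, p = inference.perm_pearson(
                model_meta.loc[mask, "age"],
                mds_model.to_numpy()[mask],
                alternative="greater",
                n_perm=cfg.n_perm,
                seed=seeds["hier_age"],
            )
            age_tests[name] = {"r": r, **_ptag(p, cfg.n_perm, seeds["hier_age"])}
        hierarchy = {
            "h_prime": h_prime,
            "linearity": _ptag(p_lin, cfg.n_randomizations, seeds["h_prime"]),
            "sex_ttest": {"t": t_stat, **_ptag(t_p, cfg.n_perm, seeds["hier_sex"])},
            "age_correlations": age_tests,
        }

        stage = "affiliative_structure"
        attrs = inference.attribute_matrices(model_meta, mds_model)
        hwi_frame = pd.DataFrame(_fill(affiliative.hwi), index=included, columns=included)
        affil_mrqap = inference.mrqap_dsp(
            _sub(hwi_frame, model_ids),
            {k: _sub(attrs[k], model_ids) for k in ["age_dist", "mds_dist", "sex_same", "kinship"]},
            n_perm=cfg.n_perm,
            seed=seeds["affil_mrqap"],
        )
        affiliative_structure = {
            "nonrandom_association": {
                "cv_observed": cv_test.observed,
                "null_mean": cv_test.null_mean,
                "null_sd": cv_test.null_sd,
                **_ptag(cv_test.p, cv_test.n_perm, seeds["cv_test"]),
            },
            "modularity_q": partition.q,
            "n_subgroups": partition.n_communities,
            "useful_subdivision": partition.q > networks.MODULARITY_USEFUL,
            "mrqap": _mrqap_block(affil_mrqap, seeds["affil_mrqap"]),
        }

        stage = "H1"
        defined = freqs_model["f10m_defined"].to_numpy()
        h1 = {}
        for key, col, alt, sname in [
            ("srf10m_vs_mds", "SRF10M", "greater", "h1_near"),
            ("f20m_vs_mds", "F20M", "less", "h1_far"),
        ]:
            y = freqs_model[col].to_numpy(dtype=float)
            mask = defined if col == "SRF10M" else np.ones(len(y), dtype=bool)
            r, p = inference.perm_pearson(
                y[mask], mds_model.to_numpy()[mask],
                alternative=alt, n_perm=cfg.n_perm, seed=seeds[sname],
            )
            h1[key] = {"r": r, "one_tailed": alt, **_ptag(p, cfg.n_perm, seeds[sname])}

        stage = "H2"
        h2 = {}
        for key, col, sname in [("srf10m", "SRF10M", "h2_near"), ("f20m", "F20M", "h2_far")]:
            y = freqs_model[col].to_numpy(dtype=float)
            mask = defined if col == "SRF10M" else np.ones(len(y), dtype=bool)
            vp = inference.variance_partition(
                y[mask],
                mds_model.to_numpy()[mask],
                labels.to_numpy()[mask],
                n_perm=cfg.n_perm,
                seed=seeds[sname],
                permute=cfg.permute_mode,
                block_names=("MDS", "subgroups"),
            )
            diag = inference.homoscedasticity_report(
                y[mask], mds_model.to_numpy()[mask], labels.to_numpy()[mask]
            )
            h2[key] = {
                "terms": {
                    t: {
                        "df": int(vp.terms.loc[t, "df"]),
                        "semipartial_r2": float(vp.terms.loc[t, "semipartial_r2"]),
                        **_ptag(float(vp.terms.loc[t, "p"]), cfg.n_perm, seeds[sname]),
                    }
                    for t in vp.terms.index
                },
                "adjusted_r2": vp.adj_r_squared,
                "model": _ptag(vp.model_p, cfg.n_perm, seeds[sname]),
                "homoscedasticity": diag,
            }

        stage = "H3"
        cooc_frame = pd.DataFrame(_fill(cooccurrence.hwi), index=included, columns=included)
        h3_mrqap = inference.mrqap_dsp(
            _sub(cooc_frame, model_ids),
            {k: _sub(attrs[k], model_ids) for k in ["mds_dist", "kinship", "age_dist", "sex_same"]},
            n_perm=cfg.n_perm,
            seed=seeds["h3_mrqap"],
        )
        excl_frame = pd.DataFrame(_fill(excluded_zone.hwi), index=included, columns=included)
        mantel_r, mantel_p = inference.mantel(
            _sub(cooc_frame, model_ids),
            _sub(excl_frame, model_ids),
            alternative="two-sided",
            n_perm=cfg.n_perm,
            seed=seeds["h3_mantel"],
        )
        overlap = overlap_percentage(
            _sub(cooc_frame, model_ids).to_numpy() > 0,
            _sub(excl_frame, model_ids).to_numpy() > 0,
        )
        h3 = {
            "mrqap": _mrqap_block(h3_mrqap, seeds["h3_mrqap"]),
            "mantel_vs_affiliative": {
                "r": mantel_r,
                **_ptag(mantel_p, cfg.n_perm, seeds["h3_mantel"]),
            },
            "overlap_percentage": overlap,
        }
    except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "descriptives": {
            "n_individuals_included": len(included),
            "n_model_individuals": len(model_ids),
            "n_scans": scans.n_scans,
            "filter_report": filter_report,
            "agonistic_report": dom_report,
        },
        "hierarchy": hierarchy,
        "affiliative_structure": affiliative_structure,
        "H1": h1,
        "H2": h2,
        "H3": h3,
        "provenance": provenance,
    }
    report = _jsonable(report)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        freqs.to_csv(outdir / "spatial_frequencies.csv")
        mds.rename("MDS").to_csv(outdir / "dominance.csv")
        (outdir / "linearity.json").write_text(json.dumps(
            {"h_prime": h_prime, "p": p_lin,
             "n_randomizations": cfg.n_randomizations, "seed": seeds["h_prime"]},
            indent=2))
        data_io.write_matrix_csv(affiliative.hwi, included, outdir / "hwi_affiliative.csv")
        data_io.write_matrix_csv(cooccurrence.hwi, included, outdir / "hwi_cooccurrence.csv")
        pd.DataFrame({
            "subgroup": partition.assignment,
            "certainty": partition.eigen_certainty,
        }).to_csv(outdir / "communities.csv")
        (outdir / "permtest.json").write_text(
            json.dumps(_jsonable(dataclasses.asdict(cv_test)), indent=2))
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _mrqap_block(result, seed: int) -> dict:
    out = {}
    for term, row in result.terms.iterrows():
        out[term] = {
            "beta": float(row["beta"]),
            "beta_std": float(row["beta_std"]),
            "partial_r": float(row["partial_r"]),
            **_ptag(float(row["p"]), result.n_perm, seed),
        }
    return {"terms": out, "r_squared": result.r_squared,
            "adjusted_r2": result.adj_r_squared}
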
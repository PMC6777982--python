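"""Cohort-level analysis: group lag differences and their structural basis.

:class:`CohortAnalysis` is the estimator tying the whole pipeline together.
Given a cohort (regions, subjects, BOLD matrices, connectomes), ``fit``:

1. estimates per-subject homotopic lag tables;
2. compares mean |lag| between stroke and control groups (pooled t test),
   tests each homotopic pair independently with FDR control, and contrasts
   affected vs unaffected subnetworks within stroke subjects (paired t,
   also restricted to intact pairs of the affected network);
3. correlates pair-level lag (log-remapped) with region-to-lesion distance;
4. computes per-subject communication-efficiency AUCs under shortest-path
   and navigation routing and correlates them with mean lag across stroke
   subjects, with age/gender-partialled variants;
5. relates pair-level lag to navigation efficiency (Spearman), homotopic
   Euclidean distance and navigation distance (Pearson on log lag), and
   partitions variance with an OLS model (Euclidean alone vs Euclidean +
   navigation distance);
6. relates mean lag and mean homotopic functional connectivity (zero-lag
   Pearson) to the ARAT motor score.

The results object carries the per-subject and per-pair frames, the
statistic table (``results``: name, estimate, p, p_adjusted, n) and a text
``summary()``. Pair-level Pearson analyses use log lag; Spearman analyses
use raw lag (rank-invariant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as lstats
from .exceptions import CollinearityError
from .comm import (
    DEFAULT_DENSITIES,
    CommunicationModel,
    euclidean_matrix,
    region_to_lesion_distance,
)
from .datatypes import homotopic_pairs, validate_regions
from .lag import DEFAULT_TAU_MAX, HomotopicLagModel, classify_affected, lag_histogram, mean_lag
from .synthetic import Cohort, gen_bold_cohort, gen_parcellation

__all__ = [
    "CohortAnalysis",
    "CohortResults",
    "run_full_analysis",
    "ttest_type1_rate",
    "null_fdr_calibration",
]


class CohortAnalysis:
    """Full statistical analysis of a (synthetic or schema-matching) cohort.

    Parameters
    ----------
    cohort : Cohort
        Regions, subjects, BOLD matrices and connectomes.
    tau_max : float
        Half-width of the lag search grid in seconds.
    densities : sequence of float
        Proportional-threshold grid for efficiency AUCs.
    fdr_q : float
        FDR level for the per-pair tests and the headline family.
    """

    def __init__(
        self,
        cohort: Cohort,
        tau_max: float = DEFAULT_TAU_MAX,
        densities=DEFAULT_DENSITIES,
        fdr_q: float = 0.05,
        compute_comm: bool = True,
    ):
        self.cohort = cohort
        self.regions = validate_regions(cohort.regions)
        self.tau_max = float(tau_max)
        self.densities = tuple(densities)
        self.fdr_q = float(fdr_q)
        self.compute_comm = compute_comm

    # -- pieces ------------------------------------------------------------

    def _lag_tables(self) -> dict[str, pd.DataFrame]:
        out = {}
        for rec in self.cohort.subjects:
            model = HomotopicLagModel(self.cohort.bold[rec.subject_id], self.regions, self.tau_max)
            out[rec.subject_id] = model.fit().table
        return out

    def _homotopic_fc(self, subject_id: str) -> float:
        """Mean zero-lag Pearson correlation over homotopic pairs."""
        bold = self.cohort.bold[subject_id]
        vals = []
        for right_id, left_id in homotopic_pairs(self.regions):
            r = np.corrcoef(bold.series(right_id), bold.series(left_id))[0, 1]
            if np.isfinite(r):
                vals.append(r)
        return float(np.mean(vals))

    # -- the analysis ------------------------------------------------------

    def fit(self) -> "CohortResults":
        cohort = self.cohort
        pairs = homotopic_pairs(self.regions)
        pair_ids = [r for r, _ in pairs]
        idx = {rid: k for k, rid in enumerate(self.regions["region_id"].to_numpy())}
        lag_tables = self._lag_tables()
        rows = []  # headline statistics

        def add(name, estimate, p=np.nan, n=0):
            rows.append((name, float(estimate), float(p), int(n)))

        # ---- subject frame ----
        srec = []
        comm_results = {}
        for rec in cohort.subjects:
            tab = lag_tables[rec.subject_id]
            entry = {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "mean_abs_lag": mean_lag(tab),
                "mean_fc": self._homotopic_fc(rec.subject_id),
                "arat": rec.arat,
                "age": rec.age_years,
                "gender": rec.gender,
                "affected_mean_lag": np.nan,
                "unaffected_mean_lag": np.nan,
                "affected_intact_mean_lag": np.nan,
                "auc_e_sp": np.nan,
                "auc_e_nav": np.nan,
            }
            if rec.group == "stroke":
                part = classify_affected(self.regions, rec)
                if part["affected"]:
                    entry["affected_mean_lag"] = mean_lag(tab, part["affected"])
                if part["unaffected"]:
                    entry["unaffected_mean_lag"] = mean_lag(tab, part["unaffected"])
                if part["affected_intact"]:
                    entry["affected_intact_mean_lag"] = mean_lag(tab, part["affected_intact"])
            if self.compute_comm and rec.subject_id in cohort.connectomes:
                res = CommunicationModel(
                    cohort.connectomes[rec.subject_id], self.densities
                ).fit()
                comm_results[rec.subject_id] = res
                entry["auc_e_sp"] = res.auc_e_sp
                entry["auc_e_nav"] = res.auc_e_nav
            srec.append(entry)
        subject_frame = pd.DataFrame(srec).set_index("subject_id", drop=False)
        stroke = subject_frame[subject_frame["group"] == "stroke"]
        control = subject_frame[subject_frame["group"] == "control"]

        # ---- group comparison of mean lag ----
        add("stroke_mean_lag_s", stroke["mean_abs_lag"].mean(), n=len(stroke))
        add("control_mean_lag_s", control["mean_abs_lag"].mean(), n=len(control))
        t, p = lstats.two_sample_t(stroke["mean_abs_lag"], control["mean_abs_lag"])
        add("lag_group_t", t, p, len(subject_frame))

        # ---- per-pair group tests with FDR ----
        prow = []
        for rid in pair_ids:
            xs = [lag_tables[s]["abs_lag_seconds"].loc[rid] for s in stroke.index]
            yc = [lag_tables[s]["abs_lag_seconds"].loc[rid] for s in control.index]
            xs = [v for v in xs if np.isfinite(v)]
            yc = [v for v in yc if np.isfinite(v)]
            tt, pp = lstats.two_sample_t(xs, yc)
            prow.append((rid, tt, pp))
        pair_tests = pd.DataFrame(prow, columns=["pair_id", "t", "p"]).set_index(
            "pair_id", drop=False
        )
        adj, rej = lstats.fdr_bh(pair_tests["p"], self.fdr_q)
        pair_tests["p_fdr"] = adj
        pair_tests["reject"] = rej
        add("pairwise_fdr_rejections", int(rej.sum()), n=len(pair_tests))

        # ---- affected vs unaffected subnetworks (stroke, paired) ----
        aff_ok = stroke.dropna(subset=["affected_mean_lag", "unaffected_mean_lag"])
        if len(aff_ok) >= 2:
            add("affected_mean_lag_s", aff_ok["affected_mean_lag"].mean(), n=len(aff_ok))
            add("unaffected_mean_lag_s", aff_ok["unaffected_mean_lag"].mean(), n=len(aff_ok))
            t, p = lstats.two_sample_t(
                aff_ok["affected_mean_lag"], aff_ok["unaffected_mean_lag"], paired=True
            )
            add("affected_vs_unaffected_t", t, p, len(aff_ok))
        intact_ok = stroke.dropna(subset=["affected_intact_mean_lag", "unaffected_mean_lag"])
        if len(intact_ok) >= 2:
            t, p = lstats.two_sample_t(
                intact_ok["affected_intact_mean_lag"],
                intact_ok["unaffected_mean_lag"],
                paired=True,
            )
            add("affected_intact_vs_unaffected_t", t, p, len(intact_ok))

        # ---- pair frame (stroke-level averages) ----
        floor = cohort.bold[cohort.subjects[0].subject_id].tr_seconds / 100.0
        pair_lag = pd.Series(
            {
                rid: np.nanmean(
                    [lag_tables[s]["abs_lag_seconds"].loc[rid] for s in stroke.index]
                )
                for rid in pair_ids
            }
        )
        lesion_d = []
        for rec in cohort.stroke:
            if rec.lesion_centroids and rec.lesion_side in ("left", "right"):
                lesion_d.append(region_to_lesion_distance(self.regions, rec))
        pair_frame = pd.DataFrame(
            {
                "pair_id": pair_ids,
                "mean_abs_lag": pair_lag,
                "log_lag": lstats.log_remap(pair_lag, floor=floor),
            }
        ).set_index("pair_id", drop=False)
        if lesion_d:
            pair_frame["lesion_distance_mm"] = pd.concat(lesion_d, axis=1).mean(axis=1)
        coords = self.regions[["x", "y", "z"]].to_numpy(dtype=float)
        dmat = euclidean_matrix(coords)
        pair_frame["homotopic_distance_mm"] = [
            dmat[idx[r], idx[l]] for r, l in pairs
        ]
        if comm_results:
            nav_eff, d_nav = {}, {}
            for rid, lid in pairs:
                i, j = idx[rid], idx[lid]
                evals = [
                    comm_results[s].pair_auc(i, j, "lambda_nav")
                    for s in stroke.index
                    if s in comm_results
                ]
                dvals = [
                    comm_results[s].pair_mean(i, j, "d_nav")
                    for s in stroke.index
                    if s in comm_results
                ]
                nav_eff[rid] = float(np.mean(evals)) if evals else np.nan
                d_nav[rid] = float(np.nanmean(dvals)) if dvals else np.nan
            pair_frame["nav_efficiency"] = pd.Series(nav_eff)
            pair_frame["d_nav_mm"] = pd.Series(d_nav)

        # ---- lag vs distance to lesion (pair level, stroke) ----
        if "lesion_distance_mm" in pair_frame:
            r, p = lstats.pearson(pair_frame["log_lag"], pair_frame["lesion_distance_mm"])
            add("lag_vs_lesion_distance_r", r, p, len(pair_frame))

        # ---- lag vs communication efficiency (subject level, stroke) ----
        eff_ok = stroke.dropna(subset=["auc_e_nav", "auc_e_sp"])
        if len(eff_ok) >= 3:
            r, p = lstats.pearson(eff_ok["mean_abs_lag"], eff_ok["auc_e_nav"])
            add("lag_vs_nav_efficiency_r", r, p, len(eff_ok))
            r, p = lstats.pearson(eff_ok["mean_abs_lag"], eff_ok["auc_e_sp"])
            add("lag_vs_sp_efficiency_r", r, p, len(eff_ok))
            cov_ok = eff_ok.dropna(subset=["age", "gender"])
            if len(cov_ok) >= 5 and cov_ok["gender"].nunique() > 1:
                Z = np.column_stack(
                    [
                        cov_ok["age"].to_numpy(dtype=float),
                        (cov_ok["gender"] == "F").to_numpy(dtype=float),
                    ]
                )
                r, p = lstats.partial_pearson(cov_ok["mean_abs_lag"], cov_ok["auc_e_nav"], Z)
                add("lag_vs_nav_efficiency_partial_r", r, p, len(cov_ok))
                r, p = lstats.partial_pearson(cov_ok["mean_abs_lag"], cov_ok["auc_e_sp"], Z)
                add("lag_vs_sp_efficiency_partial_r", r, p, len(cov_ok))

        # ---- interregional structure of lag (pair level) ----
        if "nav_efficiency" in pair_frame:
            ok = pair_frame.dropna(subset=["nav_efficiency"])
            rho, p = lstats.spearman(ok["mean_abs_lag"], ok["nav_efficiency"])
            add("pair_lag_vs_nav_efficiency_rho", rho, p, len(ok))
        r, p = lstats.pearson(pair_frame["log_lag"], pair_frame["homotopic_distance_mm"])
        add("pair_lag_vs_homotopic_distance_r", r, p, len(pair_frame))
        if "d_nav_mm" in pair_frame:
            ok = pair_frame.dropna(subset=["d_nav_mm"])
            r, p = lstats.pearson(ok["log_lag"], ok["d_nav_mm"])
            add("pair_lag_vs_nav_distance_r", r, p, len(ok))
            # on very dense graphs every homotopic pair navigates in one hop
            # and D^nav collapses onto the Euclidean distance; the variance
            # partition is then undefined and is omitted
            try:
                r2_e = lstats.glm_r2(ok["log_lag"], ok["homotopic_distance_mm"])
                r2_en = lstats.glm_r2(
                    ok["log_lag"],
                    np.column_stack([ok["homotopic_distance_mm"], ok["d_nav_mm"]]),
                )
            except CollinearityError:
                pass
            else:
                add("glm_r2_euclidean_pct", 100 * r2_e, n=len(ok))
                add("glm_r2_euclidean_plus_nav_pct", 100 * r2_en, n=len(ok))

        # ---- motor deficit ----
        arat_ok = stroke.dropna(subset=["arat"])
        if len(arat_ok) >= 3:
            rho, p = lstats.spearman(arat_ok["mean_abs_lag"], arat_ok["arat"].astype(float))
            add("lag_vs_arat_rho", rho, p, len(arat_ok))
            r, p = lstats.pearson(arat_ok["mean_fc"], arat_ok["arat"].astype(float))
            add("fc_vs_arat_r", r, p, len(arat_ok))

        results = pd.DataFrame(rows, columns=["name", "estimate", "p", "n"])
        tested = results["p"].notna()
        results["p_adjusted"] = np.nan
        if tested.any():
            adj, _ = lstats.fdr_bh(results.loc[tested, "p"], self.fdr_q)
            results.loc[tested, "p_adjusted"] = adj
        results = results[["name", "estimate", "p", "p_adjusted", "n"]]

        hist = lag_histogram(
            np.concatenate(
                [
                    lag_tables[s]["abs_lag_seconds"].dropna().to_numpy()
                    for s in subject_frame.index
                ]
            ),
            bin_width=0.5,
        )
        return CohortResults(
            self, results, subject_frame, pair_frame, pair_tests, lag_tables, hist
        )


class CohortResults:
    """Statistic table plus the intermediate frames behind it."""

    def __init__(self, model, results, subject_frame, pair_frame, pair_tests, lag_tables, histogram):
        self.model = model
        self.results = results
        self.subject_frame = subject_frame
        self.pair_frame = pair_frame
        self.pair_tests = pair_tests
        self.lag_tables = lag_tables
        self.histogram = histogram

    def __getitem__(self, name: str) -> pd.Series:
        hit = self.results[self.results["name"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]

    def estimate(self, name: str) -> float:
        return float(self[name]["estimate"])

    def plot_lag_vs_lesion_distance(self, ax=None):
        """Scatter of pair-level log lag against mean region-to-lesion distance."""
        import matplotlib.pyplot as plt

        if "lesion_distance_mm" not in self.pair_frame:
            raise ValueError("no lesion-distance data (cohort without stroke subjects)")
        if ax is None:
            _, ax = plt.subplots()
        pf = self.pair_frame
        ax.scatter(pf["lesion_distance_mm"], pf["log_lag"], s=18)
        ax.set_xlabel("distance to lesion (mm)")
        ax.set_ylabel("log lag (log s)")
        return ax

    def plot_lag_vs_efficiency(self, ax=None, measure: str = "auc_e_nav"):
        """Scatter of stroke subjects' mean |lag| against efficiency AUC."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sf = self.subject_frame
        stroke = sf[sf["group"] == "stroke"].dropna(subset=[measure])
        ax.scatter(stroke[measure], stroke["mean_abs_lag"], s=24)
        label = "navigation" if measure == "auc_e_nav" else "shortest-path"
        ax.set_xlabel(f"{label} efficiency (AUC)")
        ax.set_ylabel("mean |lag| (s)")
        return ax

    def summary(self) -> str:
        lines = ["Cohort analysis of homotopic synchronization lag", ""]
        lines.append(f"{'statistic':<38}{'estimate':>12}{'p':>12}{'p_fdr':>12}{'n':>6}")
        for _, row in self.results.iterrows():
            p = f"{row['p']:.4g}" if np.isfinite(row["p"]) else "-"
            pa = f"{row['p_adjusted']:.4g}" if np.isfinite(row["p_adjusted"]) else "-"
            lines.append(
                f"{row['name']:<38}{row['estimate']:>12.4f}{p:>12}{pa:>12}{int(row['n']):>6}"
            )
        return "\n".join(lines)


def run_full_analysis(cohort: Cohort, **kwargs) -> CohortResults:
    """One-call wrapper: ``CohortAnalysis(cohort, **kwargs).fit()``."""
    return CohortAnalysis(cohort, **kwargs).fit()


# --- calibration --------------------------------------------------------


def ttest_type1_rate(
    n_reps: int = 2000,
    n_x: int = 14,
    n_y: int = 12,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the unpaired t test on matched null normals."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(40,)))
    x = rng.standard_normal((n_reps, n_x))
    y = rng.standard_normal((n_reps, n_y))
    res = sps.ttest_ind(x, y, axis=1, equal_var=True)
    return float(np.mean(res.pvalue < alpha))


def null_fdr_calibration(
    config=None,
    n_reps: int = 100,
    q: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null cohorts with any per-pair FDR rejection.

    Each replicate draws a cohort with no planted group effect (the stroke
    lag field flattened to the control baseline), runs the per-pair
    stroke-vs-control t tests and applies BH at level ``q``.
    """
    from .datatypes import CohortConfig

    config = config or CohortConfig()
    config = config.replace(
        stroke_base_lag=0.0,
        affected_boost_lag=0.0,
        homotopic_dist_coef=0.0,
        baseline_lag=config.control_base_lag,
    )
    hits = 0
    for rep in range(n_reps):
        cfg = config.replace(seed=int(np.random.SeedSequence(seed, spawn_key=(41, rep)).generate_state(1)[0] % (2**31)))
        regions = gen_parcellation(cfg.n_pairs, cfg.seed)
        pairs = gen_bold_cohort(regions, cfg)
        tables = {}
        groups = {}
        for rec, bold in pairs:
            tables[rec.subject_id] = HomotopicLagModel(bold, regions).fit().table
            groups[rec.subject_id] = rec.group
        stroke_ids = [s for s, g in groups.items() if g == "stroke"]
        control_ids = [s for s, g in groups.items() if g == "control"]
        pvals = []
        for rid, _ in homotopic_pairs(regions):
            xs = [tables[s]["abs_lag_seconds"].loc[rid] for s in stroke_ids]
            yc = [tables[s]["abs_lag_seconds"].loc[rid] for s in control_ids]
            _, p = lstats.two_sample_t(xs, yc)
            pvals.append(p)
        _, rej = lstats.fdr_bh(pvals, q)
        hits += bool(rej.any())
    return hits / n_reps
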
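"""End-to-end analysis of pointing sessions.

The pipeline mirrors how the pointing test is scored: the eyes-open (EO)
condition gives each participant a per-target baseline direction (there is
no instrumented ground truth inside a room); every trial in every
condition is then scored as a signed circular azimuth error and a signed
elevation error against the expected direction.  For the mental-rotation
condition the expected direction can either include the imagined
90-degree rotation (default, so errors measure updating accuracy) or be
the raw baseline (unshifted mode, in which perfect mental rotators
show +/-90-degree "errors").

The statsmodels-style surface is :class:`PointingStudy` (data container)
whose :meth:`~PointingStudy.fit` returns a :class:`PointingResults` with
summaries, reliability, condition effects, correlations, a ``summary()``
table and a report bundle writer.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import circgeo
from .circgeo import (
    CircularSummary,
    circ_distance,
    circ_mean,
    detect_sensor_flips,
    great_circle_deg,
    wrap_deg,
)
from .reliability import ReliabilityResult, cronbach_alpha, test_retest, unwrap_about_circular_mean
from .session_model import CONDITIONS, DirectionAngles, Session

__all__ = [
    "PointingStudy", "PointingResults", "Baselines", "ConditionEffect",
    "trials_frame", "compute_baseline", "expected_direction", "compute_errors",
    "summarize", "target_summaries", "condition_effect", "correlate_selfreport",
    "report",
]

#: |true azimuth| at/above which a target counts as eccentric (laterality
#: annotations and the eccentric-target exclusion analysis).
ECCENTRIC_AZIMUTH_DEG = 60.0


def _bessel_circ_sd(angles_deg: np.ndarray) -> float:
    """Circular SD sqrt(-2 ln R) with a sqrt(n/(n-1)) small-sample factor.

    For concentrated data -2 ln R_hat ~ (n-1)/n * sigma^2, so the plain
    estimator is biased low at the 6-8 repetitions typical per target; the
    Bessel-style factor removes the leading bias term.
    """
    n = angles_deg.size
    summ = circ_mean(angles_deg)
    if not summ.mean_defined or n < 2:
        return math.nan
    return summ.circ_sd_deg * math.sqrt(n / (n - 1))


# ---------------------------------------------------------------------------
# Trial table
# ---------------------------------------------------------------------------

def trials_frame(sessions: list[Session]) -> pd.DataFrame:
    """Flatten sessions into one tidy trial table with derived angles."""
    rows = []
    for s in sessions:
        roster = s.roster_map()
        facing = s.layout.facing_heading_deg
        for t in s.trials:
            ang = t.vector.angles(facing)
            spec = roster.get(t.target_name)
            rows.append({
                "participant_id": s.participant_id,
                "day": t.day,
                "condition": t.condition,
                "target": t.target_name,
                "repetition": t.repetition,
                "presentation_index": t.presentation_index,
                "azimuth": ang.azimuth_deg,
                "elevation": ang.elevation_deg,
                "azimuth_defined": ang.azimuth_defined,
                "analyse_azimuth": spec.analyse_azimuth if spec else True,
                "target_azimuth": (spec.true_direction.azimuth_deg
                                   if spec and spec.true_direction else np.nan),
                "pointing_hand": s.pointing_hand,
                "rotation_side": s.rotation_side,
                "mr_side": s.mental_rotation_side,
                "pre_flagged": bool(t.flags),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

@dataclass
class Baselines:
    """Per-participant, per-target EO baseline directions plus a coverage
    report of targets with insufficient EO trials."""

    per_participant: dict[str, dict[str, DirectionAngles]]
    coverage: list[str] = field(default_factory=list)

    def __getitem__(self, participant_id: str) -> dict[str, DirectionAngles]:
        return self.per_participant[participant_id]

    def get(self, participant_id, default=None):
        return self.per_participant.get(participant_id, default)


def compute_baseline(sessions: list[Session], exclude_flagged: bool = True,
                     min_trials: int = 2) -> Baselines:
    """Pool each participant's EO trials into per-target baseline directions
    (circular mean azimuth, arithmetic mean elevation).

    Targets with fewer than ``min_trials`` EO trials are listed in the
    coverage report and omitted, not fatal.
    """
    df = trials_frame(sessions)
    df = df[df["condition"] == "EO"]
    if exclude_flagged:
        df = df[~df["pre_flagged"]]
    per: dict[str, dict[str, DirectionAngles]] = {}
    coverage: list[str] = []
    for (pid, target), grp in df.groupby(["participant_id", "target"], sort=True):
        if len(grp) < min_trials:
            coverage.append(f"{pid}/{target}: only {len(grp)} EO trials")
            continue
        el = float(grp["elevation"].mean())
        if grp["analyse_azimuth"].iloc[0] and grp["azimuth_defined"].all():
            az = circ_mean(grp["azimuth"].to_numpy()).mean_deg
            direction = DirectionAngles(az, el)
        else:
            direction = DirectionAngles(0.0, el, azimuth_defined=False)
        per.setdefault(pid, {})[target] = direction
    return Baselines(per, coverage)


def expected_direction(baseline: DirectionAngles, condition: str,
                       rotation_side: str = "right",
                       apply_mr_transform: bool = True) -> DirectionAngles:
    """Expected pointing direction for a condition given the EO baseline.

    EO/EC leave the baseline untouched.  RR (real rotation) also leaves it
    untouched: the target's world direction does not move when the body
    does, and azimuth is referenced to the original facing heading.  MR
    shifts azimuth by -90 deg for an imagined rightward rotation and +90
    for leftward (``rotation_side`` is the *imagined* side for MR); with
    ``apply_mr_transform=False`` the baseline is returned unchanged
    (unshifted baseline scoring).  Elevation is never transformed.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition != "MR" or not apply_mr_transform or not baseline.azimuth_defined:
        return baseline
    shift = -90.0 if rotation_side == "right" else 90.0
    return DirectionAngles(wrap_deg(baseline.azimuth_deg + shift),
                           baseline.elevation_deg)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

def compute_errors(sessions: list[Session], baselines: Baselines,
                   mr_transform: bool = True,
                   flip_threshold_deg: float = -15.0) -> pd.DataFrame:
    """Score every trial against its expected direction.

    Columns: signed ``azimuth_error`` (positive = right of expected; NaN
    where azimuth is non-analysable), signed ``elevation_error`` (positive
    = above), nonnegative ``total_angle_error`` (great-circle), a
    ``sensor_flip_suspect`` flag from :func:`~egopoint.circgeo.detect_sensor_flips`
    and a combined ``flagged`` column.  Trials whose target has no baseline
    are skipped (counted in ``df.attrs['n_skipped']``).
    """
    df = trials_frame(sessions)
    rows = []
    n_skipped = 0
    for _, tr in df.iterrows():
        base = baselines.get(tr["participant_id"], {}).get(tr["target"])
        if base is None:
            n_skipped += 1
            continue
        side = tr["mr_side"] if tr["condition"] == "MR" else tr["rotation_side"]
        exp = expected_direction(base, tr["condition"], side,
                                 apply_mr_transform=mr_transform)
        if exp.azimuth_defined and tr["azimuth_defined"] and tr["analyse_azimuth"]:
            az_err = float(circ_distance(tr["azimuth"], exp.azimuth_deg))
        else:
            az_err = math.nan
        el_err = float(tr["elevation"] - exp.elevation_deg)
        total = great_circle_deg(tr["azimuth"], tr["elevation"],
                                 exp.azimuth_deg, exp.elevation_deg)
        rows.append({
            "participant_id": tr["participant_id"],
            "day": tr["day"],
            "condition": tr["condition"],
            "target": tr["target"],
            "repetition": tr["repetition"],
            "azimuth_error": az_err,
            "elevation_error": el_err,
            "total_angle_error": total,
            "elevation": tr["elevation"],
            "target_azimuth": tr["target_azimuth"],
            "pointing_hand": tr["pointing_hand"],
            "pre_flagged": tr["pre_flagged"],
        })
    out = pd.DataFrame(rows)
    if len(out):
        az = out["azimuth_error"].to_numpy()
        flips = detect_sensor_flips(np.nan_to_num(az), out["elevation"].to_numpy(),
                                    threshold_deg=flip_threshold_deg)
        out["sensor_flip_suspect"] = flips & ~np.isnan(az)
        out["flagged"] = out["sensor_flip_suspect"] | out["pre_flagged"]
    out.attrs["n_skipped"] = n_skipped
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(errors: pd.DataFrame, by=("condition",),
              exclude_flagged: bool = True) -> pd.DataFrame:
    """Grouped error summaries: mean absolute and SD of azimuth (circular)
    and elevation (linear) errors.

    When grouping by target, eccentric targets (|true azimuth| >=
    ``ECCENTRIC_AZIMUTH_DEG``) contralateral to the pointing hand carry a
    laterality annotation — these are the targets whose azimuth
    variability is inflated.
    """
    if errors.empty:
        raise ValueError("no error records to summarize")
    df = errors[~errors["flagged"]] if exclude_flagged else errors
    by = list(by)
    rows = []
    for key, grp in df.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        az = grp["azimuth_error"].dropna().to_numpy()
        el = grp["elevation_error"].to_numpy()
        row = dict(zip(by, key))
        row["mean_abs_azimuth_error"] = float(np.mean(np.abs(az))) if az.size else math.nan
        row["azimuth_sd"] = _bessel_circ_sd(az) if az.size >= 2 else math.nan
        row["mean_abs_elevation_error"] = float(np.mean(np.abs(el)))
        row["elevation_sd"] = float(np.std(el, ddof=1)) if el.size >= 2 else math.nan
        row["n"] = int(len(grp))
        if "target" in by:
            t_az = grp["target_azimuth"].iloc[0]
            hand = grp["pointing_hand"].iloc[0] if grp["pointing_hand"].nunique() == 1 else None
            ecc = bool(np.isfinite(t_az) and abs(t_az) >= ECCENTRIC_AZIMUTH_DEG)
            contra = bool(ecc and hand is not None
                          and ((t_az < 0) == (hand == "right")))
            row["eccentric"] = ecc
            row["contralateral"] = contra
        rows.append(row)
    return pd.DataFrame(rows)


def target_summaries(sessions: list[Session],
                     exclude_flagged: bool = True) -> pd.DataFrame:
    """Per (participant, condition, target) raw-angle summaries: circular
    azimuth mean/R/SD and linear elevation mean/SD.

    This is the quantity behind the per-target variability profile of the
    baseline condition (azimuth SD uses the Bessel-corrected circular SD).
    """
    df = trials_frame(sessions)
    if exclude_flagged:
        df = df[~df["pre_flagged"]]
    rows = []
    for (pid, cond, target), grp in df.groupby(
            ["participant_id", "condition", "target"], sort=True):
        az = grp.loc[grp["azimuth_defined"] & grp["analyse_azimuth"],
                     "azimuth"].to_numpy()
        el = grp["elevation"].to_numpy()
        if az.size:
            summ = circ_mean(az)
            az_mean, az_R = summ.mean_deg, summ.resultant_length
            az_sd = _bessel_circ_sd(az) if az.size >= 2 else math.nan
        else:
            az_mean = az_R = az_sd = math.nan
        rows.append({
            "participant_id": pid, "condition": cond, "target": target,
            "azimuth_mean": az_mean, "azimuth_R": az_R, "azimuth_sd": az_sd,
            "elevation_mean": float(el.mean()),
            "elevation_sd": float(np.std(el, ddof=1)) if el.size >= 2 else math.nan,
            "n_trials": int(len(grp)),
            "n_flagged": int(grp["pre_flagged"].sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Condition effect (one-way repeated-measures ANOVA + permutation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionEffect:
    f_value: float
    df_between: int
    df_within: int
    p_parametric: float
    p_permutation: float
    condition_means: dict[str, float]
    n_perm: int


def _rm_anova_f(x: np.ndarray) -> np.ndarray:
    """One-way repeated-measures F over the last two axes (subjects x
    conditions); broadcasts over leading axes (used for permutations)."""
    s, c = x.shape[-2], x.shape[-1]
    grand = x.mean(axis=(-1, -2), keepdims=True)
    cond = x.mean(axis=-2, keepdims=True)
    subj = x.mean(axis=-1, keepdims=True)
    ss_cond = (s * (cond - grand) ** 2).sum(axis=(-1, -2))
    ss_subj = (c * (subj - grand) ** 2).sum(axis=(-1, -2))
    ss_tot = ((x - grand) ** 2).sum(axis=(-1, -2))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = c - 1, (c - 1) * (s - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ss_cond / df1) / (ss_err / df2)


def condition_effect(means: pd.DataFrame, n_perm: int = 999,
                     seed: int = 0) -> ConditionEffect:
    """Effect of condition on per-participant mean errors.

    ``means`` is a complete wide table (rows = participants, columns =
    conditions).  Reports the one-way repeated-measures ANOVA F with
    (c-1, (c-1)(s-1)) degrees of freedom, the parametric p, and a
    within-participant label-permutation p (resolution 1/(n_perm+1)).
    """
    x = means.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need >= 3 participants and >= 2 conditions")
    if np.any(~np.isfinite(x)):
        raise ValueError("incomplete cells: impute or exclude participants "
                         "with missing conditions before calling condition_effect")
    s, c = x.shape
    f_obs = float(_rm_anova_f(x))
    df1, df2 = c - 1, (c - 1) * (s - 1)
    p_param = float(stats.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0

    rng = np.random.default_rng(seed)
    idx = rng.permuted(np.broadcast_to(np.arange(c), (n_perm, s, c)).copy(), axis=2)
    perms = np.take_along_axis(np.broadcast_to(x, (n_perm, s, c)), idx, axis=2)
    f_perm = _rm_anova_f(perms)
    p_perm = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (n_perm + 1.0)
    return ConditionEffect(
        f_value=f_obs, df_between=df1, df_within=df2,
        p_parametric=p_param, p_permutation=float(p_perm),
        condition_means={col: float(means[col].mean()) for col in means.columns},
        n_perm=n_perm)


# ---------------------------------------------------------------------------
# Self-report correlations
# ---------------------------------------------------------------------------

def correlate_selfreport(metrics: pd.DataFrame, scores: pd.DataFrame,
                         pairs: list[tuple[str, str]] | None = None,
                         ) -> pd.DataFrame:
    """Pearson correlations between pointing metrics and questionnaire
    scores, matched on ``participant_id``.

    Missing participants are dropped pairwise (counts in ``n``); raw
    two-sided p-values are reported alongside Benjamini-Hochberg adjusted
    ones.  Pairs with zero variance get an ``undefined`` flag.
    """
    from statsmodels.stats.multitest import multipletests

    merged = metrics.merge(scores, on="participant_id", how="inner",
                           suffixes=("", "_score"))
    if pairs is None:
        mcols = [c for c in metrics.columns if c != "participant_id"]
        scols = [c for c in scores.columns if c != "participant_id"]
        pairs = [(m, s) for m in mcols for s in scols]
    rows = []
    for m, sc in pairs:
        sub = merged[[m, sc]].dropna()
        n = len(sub)
        if n < 4:
            rows.append({"metric": m, "score": sc, "r": math.nan, "p": math.nan,
                         "n": n, "undefined": True})
            continue
        x, y = sub[m].to_numpy(), sub[sc].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"metric": m, "score": sc, "r": math.nan, "p": math.nan,
                         "n": n, "undefined": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"metric": m, "score": sc, "r": float(r), "p": float(p),
                     "n": n, "undefined": False})
    out = pd.DataFrame(rows)
    ok = ~out["undefined"]
    out["p_fdr"] = math.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

#: default metric/questionnaire pairs examined when scores are provided
DEFAULT_CORRELATION_PAIRS = [
    ("EC_mean_abs_azimuth_error", "sbsod"),
    ("RR_mean_abs_azimuth_error", "perspective_taking"),
    ("MR_mean_abs_azimuth_error", "perspective_taking"),
    ("EO_azimuth_sd", "sbsod"),
]


class PointingStudy:
    """A cohort of pointing sessions, optionally with questionnaire scores.

    Parameters
    ----------
    sessions : list of Session
        One entry per participant-day.
    scores : DataFrame, optional
        One row per participant: ``participant_id, sbsod,
        perspective_taking, wayfinding, spatial_anxiety``.
    """

    def __init__(self, sessions: list[Session],
                 scores: pd.DataFrame | None = None):
        if not sessions:
            raise ValueError("need at least one session")
        self.sessions = list(sessions)
        self.scores = scores

    @classmethod
    def from_files(cls, session_paths, scores_csv=None,
                   strict: bool = True) -> "PointingStudy":
        from .session_model import read_session
        sessions = [read_session(p, strict=strict) for p in session_paths]
        scores = pd.read_csv(scores_csv) if scores_csv else None
        return cls(sessions, scores=scores)

    @property
    def participants(self) -> list[str]:
        return sorted({s.participant_id for s in self.sessions})

    def fit(self, mr_transform: bool = True, exclude_flagged: bool = True,
            n_perm: int = 999, seed: int = 0,
            correlation_pairs: list[tuple[str, str]] | None = None,
            ) -> "PointingResults":
        """Run the full pipeline and return a results object."""
        baselines = compute_baseline(self.sessions,
                                     exclude_flagged=exclude_flagged)
        errors = compute_errors(self.sessions, baselines,
                                mr_transform=mr_transform)
        tsum = target_summaries(self.sessions, exclude_flagged=exclude_flagged)
        cond_sum = summarize(errors, by=("condition",),
                             exclude_flagged=exclude_flagged)

        # per-participant condition means of |azimuth error|
        df = errors[~errors["flagged"]] if exclude_flagged else errors
        pc = (df.dropna(subset=["azimuth_error"])
                .assign(abs_az=lambda d: d["azimuth_error"].abs())
                .groupby(["participant_id", "condition"])["abs_az"].mean()
                .unstack("condition"))
        cond_cols = [c for c in CONDITIONS if c in pc.columns]
        pc = pc[cond_cols]
        effect = None
        if len(cond_cols) >= 2 and pc.dropna().shape[0] >= 3:
            effect = condition_effect(pc.dropna(), n_perm=n_perm, seed=seed)

        rel = self._reliability(tsum)
        correlations = None
        if self.scores is not None:
            metrics = self._participant_metrics(errors, tsum,
                                                exclude_flagged=exclude_flagged)
            pairs = correlation_pairs or [
                p for p in DEFAULT_CORRELATION_PAIRS
                if p[0] in metrics.columns and p[1] in self.scores.columns]
            correlations = correlate_selfreport(metrics, self.scores, pairs)

        return PointingResults(
            study=self, baselines=baselines, errors=errors,
            target_summaries=tsum, condition_summary=cond_sum,
            participant_condition_means=pc, condition_effect=effect,
            reliability=rel, correlations=correlations,
            options={"mr_transform": mr_transform,
                     "exclude_flagged": exclude_flagged,
                     "n_perm": n_perm, "seed": seed},
        )

    def _reliability(self, tsum: pd.DataFrame) -> dict[str, ReliabilityResult]:
        """Internal consistency over targets (participants x targets matrix
        of EO per-target means) and EO day-1 vs day-2 test-retest."""
        rel: dict[str, ReliabilityResult] = {}
        eo = tsum[tsum["condition"] == "EO"]
        az = eo.pivot_table(index="participant_id", columns="target",
                            values="azimuth_mean").dropna(axis=1)
        el = eo.pivot_table(index="participant_id", columns="target",
                            values="elevation_mean").dropna(axis=1)
        if az.shape[0] >= 2 and az.shape[1] >= 2:
            rel["internal_azimuth"] = cronbach_alpha(
                unwrap_about_circular_mean(az.to_numpy()))
        if el.shape[0] >= 2 and el.shape[1] >= 2:
            rel["internal_elevation"] = cronbach_alpha(el.to_numpy())

        # day-wise EO means for test-retest
        df = trials_frame(self.sessions)
        eo_t = df[(df["condition"] == "EO") & df["azimuth_defined"]
                  & df["analyse_azimuth"]]
        day_means = (eo_t.groupby(["participant_id", "target", "day"])["azimuth"]
                     .apply(lambda a: circ_mean(a.to_numpy()).mean_deg)
                     .unstack("day"))
        if {1, 2}.issubset(day_means.columns):
            both = day_means[[1, 2]].dropna()
            if len(both) >= 3:
                rel["test_retest_azimuth"] = test_retest(
                    both[1], both[2], circular=True)
        return rel

    def _participant_metrics(self, errors: pd.DataFrame, tsum: pd.DataFrame,
                             exclude_flagged: bool = True) -> pd.DataFrame:
        df = errors[~errors["flagged"]] if exclude_flagged else errors
        per = (df.dropna(subset=["azimuth_error"])
                 .assign(abs_az=lambda d: d["azimuth_error"].abs(),
                         abs_el=lambda d: d["elevation_error"].abs())
                 .groupby(["participant_id", "condition"])
                 .agg(az=("abs_az", "mean"), el=("abs_el", "mean"))
                 .unstack("condition"))
        out = pd.DataFrame({"participant_id": per.index})
        for cond in CONDITIONS:
            if ("az", cond) in per.columns:
                out[f"{cond}_mean_abs_azimuth_error"] = per[("az", cond)].to_numpy()
                out[f"{cond}_mean_abs_elevation_error"] = per[("el", cond)].to_numpy()
        eo_sd = (tsum[tsum["condition"] == "EO"]
                 .groupby("participant_id")[["azimuth_sd", "elevation_sd"]].mean())
        out = out.merge(eo_sd.rename(columns={"azimuth_sd": "EO_azimuth_sd",
                                              "elevation_sd": "EO_elevation_sd"}),
                        on="participant_id", how="left")
        return out


@dataclass
class PointingResults:
    """Fitted results of a pointing study; returned by ``PointingStudy.fit``."""

    study: PointingStudy
    baselines: Baselines
    errors: pd.DataFrame
    target_summaries: pd.DataFrame
    condition_summary: pd.DataFrame
    participant_condition_means: pd.DataFrame
    condition_effect: ConditionEffect | None
    reliability: dict[str, ReliabilityResult]
    correlations: pd.DataFrame | None
    options: dict

    def summary(self) -> str:
        """Human-readable results table."""
        lines = []
        n_part = len(self.study.participants)
        lines.append("Egocentric pointing study results")
        lines.append("=" * 49)
        lines.append(f"Participants: {n_part}   Trials: {len(self.errors)}   "
                     f"MR transform: {self.options['mr_transform']}")
        lines.append("")
        lines.append("Condition summaries (vs. EO baseline)")
        lines.append("-" * 49)
        lines.append(f"{'cond':<5}{'|az err|':>10}{'az SD':>9}"
                     f"{'|el err|':>10}{'el SD':>9}{'n':>6}")
        for _, r in self.condition_summary.iterrows():
            lines.append(f"{r['condition']:<5}{r['mean_abs_azimuth_error']:>10.2f}"
                         f"{r['azimuth_sd']:>9.2f}"
                         f"{r['mean_abs_elevation_error']:>10.2f}"
                         f"{r['elevation_sd']:>9.2f}{int(r['n']):>6d}")
        if self.condition_effect is not None:
            e = self.condition_effect
            lines.append("")
            lines.append(
                f"rm-ANOVA condition effect: F({e.df_between}, {e.df_within}) "
                f"= {e.f_value:.2f}, p = {e.p_parametric:.4f} "
                f"(permutation p = {e.p_permutation:.4f}, {e.n_perm} resamples)")
        if self.reliability:
            lines.append("")
            lines.append("Reliability")
            lines.append("-" * 49)
            for name, r in self.reliability.items():
                ci = (f" CI [{r.ci_low:.4f}, {r.ci_high:.4f}]"
                      if np.isfinite(r.ci_low) else "")
                lines.append(f"{name:<24}{r.form:<8}{r.estimate:.4f}{ci}")
        if self.correlations is not None and len(self.correlations):
            lines.append("")
            lines.append("Self-report correlations (Pearson)")
            lines.append("-" * 49)
            for _, r in self.correlations.iterrows():
                if r["undefined"]:
                    lines.append(f"{r['metric']} x {r['score']}: undefined")
                else:
                    lines.append(f"{r['metric']} x {r['score']}: "
                                 f"r = {r['r']:+.3f}, p = {r['p']:.3f}, "
                                 f"n = {int(r['n'])}")
        return "\n".join(lines)

    def save_report(self, outdir, figures: bool = True) -> dict:
        """Write the report bundle (CSV tables, JSON summary, figures,
        manifest); returns the manifest."""
        return report(self, outdir, figures=figures)


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def report(results: PointingResults, outdir, figures: bool = True) -> dict:
    """Emit the report bundle: per-participant and cohort CSV tables, a
    machine-readable JSON summary, polar-histogram and per-target SD
    figures, and a manifest with content hashes for the text artifacts."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[dict] = []
    skipped: list[str] = []

    def _write_csv(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        artifacts.append({"path": name, "sha256": _sha256(path)})

    _write_csv(results.errors, "errors.csv")
    _write_csv(results.target_summaries, "target_summaries.csv")
    _write_csv(results.condition_summary, "condition_summary.csv")
    _write_csv(results.participant_condition_means.reset_index(),
               "participant_condition_means.csv")
    if results.correlations is not None:
        _write_csv(results.correlations, "correlations.csv")
    else:
        skipped.append("correlations (no questionnaire scores)")

    summary = {
        "participants": results.study.participants,
        "options": results.options,
        "conditions": results.condition_summary.to_dict(orient="records"),
        "reliability": {
            k: {"estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "form": r.form, "n_subjects": r.n_subjects, "n_items": r.n_items}
            for k, r in results.reliability.items()},
        "condition_effect": None,
        "coverage_issues": results.baselines.coverage,
    }
    if results.condition_effect is not None:
        e = results.condition_effect
        summary["condition_effect"] = {
            "f_value": e.f_value, "df_between": e.df_between,
            "df_within": e.df_within, "p_parametric": e.p_parametric,
            "p_permutation": e.p_permutation, "n_perm": e.n_perm,
            "condition_means": e.condition_means}
    else:
        skipped.append("condition_effect (insufficient complete cells)")
    spath = out / "summary.json"
    with open(spath, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, allow_nan=True)
        fh.write("\n")
    artifacts.append({"path": "summary.json", "sha256": _sha256(spath)})

    if figures:
        fig_paths = _report_figures(results, out)
        artifacts.extend({"path": p} for p in fig_paths)
    else:
        skipped.append("figures (disabled)")

    manifest = {"artifacts": artifacts, "skipped": skipped,
                "options": results.options}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest


def _report_figures(results: PointingResults, out) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: list[str] = []
    df = results.errors
    eo = df[df["condition"] == "EO"]

    # polar histograms of raw-angle spread around baseline, per target/plane
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    for plane, col in (("azimuth", "azimuth_error"), ("elevation", "elevation_error")):
        targets = sorted(eo["target"].unique())
        if not targets:
            continue
        ncol = 5
        nrow = int(np.ceil(len(targets) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow),
                                 subplot_kw={"projection": "polar"})
        for ax, target in zip(np.ravel(axes), targets):
            vals = eo.loc[eo["target"] == target, col].dropna().to_numpy()
            if vals.size:
                ax.hist(np.radians(vals), bins=36)
            ax.set_title(target, fontsize=7)
            ax.set_theta_zero_location("N")
            ax.set_theta_direction(-1)
        for ax in np.ravel(axes)[len(targets):]:
            ax.set_axis_off()
        name = f"figures/polar_{plane}_EO.png"
        fig.suptitle(f"EO {plane} error distributions per target")
        fig.tight_layout()
        fig.savefig(out / name, dpi=100)
        plt.close(fig)
        paths.append(name)

    # per-target SD profile (baseline variability)
    tsum = results.target_summaries
    eo_sum = tsum[tsum["condition"] == "EO"]
    if len(eo_sum):
        agg = eo_sum.groupby("target")[["azimuth_sd", "elevation_sd"]].mean()
        fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
        axes[0].bar(agg.index, agg["elevation_sd"])
        axes[0].set_ylabel("elevation SD (deg)")
        axes[1].bar(agg.index, agg["azimuth_sd"])
        axes[1].set_ylabel("azimuth SD (deg)")
        axes[1].tick_params(axis="x", rotation=75)
        fig.suptitle("Per-target pointing variability (EO)")
        fig.tight_layout()
        fig.savefig(out / "figures/target_sd_EO.png", dpi=100)
        plt.close(fig)
        paths.append("figures/target_sd_EO.png")
    return paths
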
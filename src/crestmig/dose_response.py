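"""Dose-response endpoints for the migration assay.

Per-well counts are normalized to the same-plate control mean (percent of
control), tested by one-way ANOVA with Dunnett's many-to-one post-hoc
comparisons, and summarized as the assay's standard toxicological endpoints:

* LOAEL — the lowest tested concentration with a significant *reduction*
  (adjusted p <= alpha and mean below control);
* EC75 — the concentration at which the mean normalized migration first
  crosses 75% of control, located by linear interpolation on
  log10(concentration) (a Hill fit is available as an alternative);
* impairment flags — viability impaired below 90% of control, migration
  impaired below 75% (strict inequalities, so boundary values are unflagged).

Also included: EdU proliferation fractions and transwell field-count
summaries with Welch t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EndpointSummary",
    "normalize_to_control",
    "anova_dunnett",
    "dunnett_critical_value",
    "determine_loael",
    "determine_ec75",
    "classify_endpoint",
    "proliferation_fraction",
    "transwell_summary",
    "summarize_endpoint",
]

#: fixed internal seed for the Monte-Carlo multivariate-t integration behind
#: Dunnett p-values; at scipy's default sample size the p-value Monte-Carlo
#: error is ~2e-3.
DUNNETT_MC_SEED = 190_443_021

MIGRATION_IMPAIRMENT_PCT = 75.0
VIABILITY_IMPAIRMENT_PCT = 90.0


@dataclass
class EndpointSummary:
    """LOAEL / EC75 and per-concentration statistics for one endpoint."""

    endpoint: str
    loael_pM: float | None  # None -> "none detected"
    ec75_pM: float | None  # None -> "> max tested"
    table: pd.DataFrame  # concentration_pM, mean_pct, sd_pct, n, p_adj, flag

    @property
    def loael_label(self) -> str:
        return "none detected" if self.loael_pM is None else f"{self.loael_pM:g} pM"

    @property
    def ec75_label(self) -> str:
        return "> max tested" if self.ec75_pM is None else f"{self.ec75_pM:g} pM"


def normalize_to_control(
    wells: pd.DataFrame,
    value_column: str,
    plate_column: str = "plate_id",
    concentration_column: str = "concentration_pM",
) -> pd.DataFrame:
    """Express each well's count as percent of its plate's control mean.

    Control wells are those with concentration 0.  Returns the input with an
    added ``pct_of_control`` column.
    """
    wells = wells.copy()
    out = np.empty(len(wells))
    for plate, grp in wells.groupby(plate_column):
        ctrl = grp.loc[grp[concentration_column] == 0, value_column]
        if ctrl.empty:
            raise ValueError(f"plate {plate!r} has no control (0 pM) wells")
        ctrl_mean = float(ctrl.mean())
        if ctrl_mean == 0:
            raise ValueError(f"plate {plate!r} control mean is zero")
        out[wells[plate_column] == plate] = (
            wells.loc[wells[plate_column] == plate, value_column] / ctrl_mean * 100.0
        )
    wells["pct_of_control"] = out
    return wells


def anova_dunnett(
    table: pd.DataFrame,
    value_column: str = "pct_of_control",
    concentration_column: str = "concentration_pM",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA plus Dunnett many-to-one comparisons against control.

    Returns one row per non-zero concentration with group mean/SD, the ANOVA
    F/p (repeated on each row for convenience), the Dunnett-adjusted two-sided
    p-value, and a significance flag at ``alpha``.  The Dunnett distribution
    (equicorrelated multivariate t for balanced designs, pairwise correlations
    otherwise) is integrated by Monte Carlo with a fixed internal seed, so
    repeated calls are reproducible.
    """
    groups = []
    concs = sorted(c for c in table[concentration_column].unique() if c > 0)
    control = table.loc[table[concentration_column] == 0, value_column].to_numpy()
    if control.size < 2:
        raise ValueError("need >= 2 control replicates")
    for c in concs:
        g = table.loc[table[concentration_column] == c, value_column].to_numpy()
        if g.size < 2:
            raise ValueError(f"concentration {c} has < 2 replicates")
        groups.append(g)
    if not groups:
        raise ValueError("no treated concentrations present")

    all_groups = [control] + groups
    if all(np.ptp(g) == 0 for g in all_groups):
        raise ValueError("zero within-group variance in every group")

    f_stat, f_p = stats.f_oneway(*all_groups)
    res = stats.dunnett(
        *groups, control=control, rng=np.random.default_rng(DUNNETT_MC_SEED)
    )
    rows = []
    for c, g, p_adj in zip(concs, groups, res.pvalue):
        rows.append(
            {
                "concentration_pM": c,
                "mean_pct": float(np.mean(g)),
                "sd_pct": float(np.std(g, ddof=1)),
                "n": int(g.size),
                "anova_F": float(f_stat),
                "anova_p": float(f_p),
                "p_adj": float(p_adj),
                "significant": bool(p_adj <= alpha),
            }
        )
    return pd.DataFrame(rows)


def dunnett_critical_value(
    k: int,
    df: int,
    alpha: float = 0.05,
    n_mc: int = 200_000,
    seed: int = DUNNETT_MC_SEED,
) -> float:
    """Two-sided Dunnett critical value for k balanced comparisons.

    Simulates max_i |(Z_i - Z_0)/(sqrt(2) S)| — the null law of the Dunnett
    statistics for a balanced one-way layout with pooled-variance df — and
    returns its (1 - alpha) quantile.  The familywise rejection rule
    "any adjusted p <= alpha" is equivalent to max |t_i| exceeding this value.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, k + 1))
    s = np.sqrt(rng.chisquare(df, size=n_mc) / df)
    t = (z[:, 1:] - z[:, :1]) / (math.sqrt(2.0) * s[:, None])
    tmax = np.abs(t).max(axis=1)
    return float(np.quantile(tmax, 1.0 - alpha))


def determine_loael(
    dunnett_table: pd.DataFrame,
    alpha: float = 0.05,
    control_mean: float = 100.0,
) -> float | None:
    """Lowest concentration with adjusted p <= alpha and mean below control.

    Returns None ("none detected") when no tested concentration qualifies.
    The directionality requirement keeps significant *increases* from
    counting as adverse.
    """
    t = dunnett_table.sort_values("concentration_pM")
    hit = t[(t["p_adj"] <= alpha) & (t["mean_pct"] < control_mean)]
    if hit.empty:
        return None
    return float(hit["concentration_pM"].iloc[0])


def _hill_response(c, ec, h, emax):
    return 100.0 * (1.0 - emax * c**h / (c**h + ec**h))


def determine_ec75(
    means: pd.DataFrame,
    threshold: float = MIGRATION_IMPAIRMENT_PCT,
    concentration_column: str = "concentration_pM",
    mean_column: str = "mean_pct",
    method: str = "interpolation",
) -> float | None:
    """Concentration at the first downward crossing of ``threshold`` percent.

    ``interpolation`` (default) interpolates the mean response linearly
    against log10(concentration) between the bracketing tested
    concentrations; the control (0 pM) is excluded from the log axis.  If a
    tested mean equals the threshold exactly, that concentration is returned.
    If the curve never falls below the threshold the result is None
    ("> max tested"); if the response is already below threshold at the lowest
    tested concentration, that concentration is returned.  ``method="hill"``
    instead fits a descending Hill curve and solves it for the threshold.
    """
    t = means[means[concentration_column] > 0].sort_values(concentration_column)
    if t.empty:
        raise ValueError("no positive tested concentrations")
    if (t[concentration_column] <= 0).any():
        raise ValueError("log-scale interpolation requires positive concentrations")
    conc = t[concentration_column].to_numpy(dtype=float)
    resp = t[mean_column].to_numpy(dtype=float)

    if method == "hill":
        try:
            popt, _ = optimize.curve_fit(
                _hill_response,
                conc,
                resp,
                p0=[np.median(conc), 1.0, 1.0],
                bounds=([1e-9, 0.1, 0.0], [np.inf, 10.0, 1.0]),
                maxfev=10_000,
            )
        except RuntimeError:
            return None
        ec, h, emax = popt
        floor = 100.0 * (1.0 - emax)
        if floor >= threshold or _hill_response(conc[-1], *popt) > threshold:
            return None
        lo, hi = conc[0] * 1e-6, conc[-1]
        if _hill_response(lo, *popt) <= threshold:
            return float(conc[0])
        return float(
            optimize.brentq(lambda c: _hill_response(c, *popt) - threshold, lo, hi)
        )

    if method != "interpolation":
        raise ValueError(f"unknown EC75 method {method!r}")

    exact = conc[resp == threshold]
    below = resp < threshold
    first_below = int(np.argmax(below)) if below.any() else None
    if exact.size and (first_below is None or exact[0] <= conc[first_below]):
        return float(exact[0])
    if first_below is None:
        return None
    if first_below == 0:
        return float(conc[0])
    c_hi, c_lo = conc[first_below - 1], conc[first_below]
    r_hi, r_lo = resp[first_below - 1], resp[first_below]
    frac = (r_hi - threshold) / (r_hi - r_lo)
    log_ec = math.log10(c_hi) + frac * (math.log10(c_lo) - math.log10(c_hi))
    return float(10.0**log_ec)


def classify_endpoint(
    migration_pct: float, viability_pct: float
) -> dict[str, bool]:
    """Impairment flags at the assay's prediction-model thresholds.

    Migration counts as impaired strictly below 75% of control, viability
    strictly below 90%; the ``migration_specific`` label marks the
    migrastatic signature (migration impaired at a viability-tolerated
    concentration).
    """
    mig = migration_pct < MIGRATION_IMPAIRMENT_PCT
    via = viability_pct < VIABILITY_IMPAIRMENT_PCT
    return {
        "migration_impaired": bool(mig),
        "viability_impaired": bool(via),
        "migration_specific": bool(mig and not via),
    }


def proliferation_fraction(n_edu_pos: int, n_nuclei: int) -> float:
    """Percent EdU-positive nuclei among all Hoechst-positive nuclei."""
    if n_nuclei <= 0:
        raise ValueError("n_nuclei must be positive")
    if not (0 <= n_edu_pos <= n_nuclei):
        raise ValueError("n_edu_pos must lie in [0, n_nuclei]")
    return 100.0 * n_edu_pos / n_nuclei


def transwell_summary(
    fields: pd.DataFrame,
    control_label: str = "control",
    condition_column: str = "condition",
    replicate_column: str = "replicate",
    count_column: str = "count",
) -> pd.DataFrame:
    """Summarize transwell field counts and test each condition vs control.

    The replicate value is the mean of its imaged fields; the condition
    summary is mean +/- SD across replicates, with a Welch t-test against the
    control condition.
    """
    if fields.empty:
        raise ValueError("no transwell counts provided")
    reps = (
        fields.groupby([condition_column, replicate_column])[count_column]
        .mean()
        .reset_index()
    )
    if control_label not in set(reps[condition_column]):
        raise ValueError(f"control condition {control_label!r} missing")
    ctrl = reps.loc[reps[condition_column] == control_label, count_column].to_numpy()
    rows = []
    for cond, grp in reps.groupby(condition_column):
        vals = grp[count_column].to_numpy()
        if cond == control_label or len(vals) < 2 or len(ctrl) < 2:
            p = np.nan if cond != control_label else np.nan
        else:
            p = float(stats.ttest_ind(vals, ctrl, equal_var=False).pvalue)
        rows.append(
            {
                "condition": cond,
                "n_replicates": int(len(vals)),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "p_vs_control": p,
            }
        )
    return pd.DataFrame(rows)


def summarize_endpoint(
    wells: pd.DataFrame,
    endpoint: str,
    alpha: float = 0.05,
    ec75_method: str = "interpolation",
) -> EndpointSummary:
    """Normalized table -> Dunnett table -> LOAEL/EC75 for one endpoint.

    ``wells`` must carry ``plate_id``, ``concentration_pM`` and the raw count
    column for the endpoint (``n_migrated`` for migration, ``n_viable_total``
    for viability).
    """
    value_column = {"migration": "n_migrated", "viability": "n_viable_total"}.get(
        endpoint, endpoint
    )
    norm = normalize_to_control(wells, value_column)
    dt = anova_dunnett(norm, alpha=alpha)
    loael = determine_loael(dt, alpha=alpha)
    ec75 = determine_ec75(dt, method=ec75_method)
    impair_thr = (
        VIABILITY_IMPAIRMENT_PCT if endpoint == "viability" else MIGRATION_IMPAIRMENT_PCT
    )
    dt = dt.copy()
    dt["flag"] = dt["mean_pct"] < impair_thr
    return EndpointSummary(endpoint=endpoint, loael_pM=loael, ec75_pM=ec75, table=dt)
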
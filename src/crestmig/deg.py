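"""Paired moderated-t differential expression, FDR gating and enrichment.

The design is the lot-paired one the transcriptomics arm of the study used:
each cell lot contributes one treated and one control array, and inference is
on the per-probe paired log2 differences.  The per-probe variance is shrunk
toward a global prior by the standard empirical-Bayes argument: sample
variances are modelled as scaled chi-square draws around probe-level true
variances that follow a scaled inverse-chi-square prior with hyperparameters
(d0, s0^2), estimated in closed form by method of moments on the
log-variances.  The moderated t statistic

    t_g = logFC_g / (s_tilde_g / sqrt(n)),
    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),   d = n - 1,

is referred to a t distribution with d0 + d degrees of freedom (a normal law
when d0 is infinite).  Differentially expressed probes must pass both the
Benjamini-Hochberg FDR gate (adjusted p <= 0.05) and a fold-change gate
(FC >= 1.8 or <= 0.55), matching the screening convention of the study.

Gene-set over-representation is one-sided Fisher's exact (hypergeometric
upper tail), BH-adjusted across sets, with up- and down-regulated gene lists
analyzed separately, plus a rollup of significant sets into six superordinate
cell-biological classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ModeratedTParams",
    "paired_differences",
    "fit_variance_prior",
    "paired_moderated_t",
    "bh_adjust",
    "call_degs",
    "fisher_enrichment",
    "superordinate_rollup",
    "read_expression",
    "read_design",
    "read_gmt",
    "SUPERORDINATE_CLASSES",
]

SUPERORDINATE_CLASSES = (
    "migration/adhesion",
    "metabolism",
    "differentiation",
    "signaling",
    "stress response",
    "others",
)

FC_UP_DEFAULT = 1.8
FC_DOWN_DEFAULT = 0.55
ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class ModeratedTParams:
    """Empirical-Bayes hyperparameters: prior df d0 (inf allowed), prior
    variance s0^2, and the common residual df per probe."""

    d0: float
    s0_sq: float
    d: int

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be non-negative")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


# ---------------------------------------------------------------------------
# paired design
# ---------------------------------------------------------------------------


def paired_differences(values: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-probe treated-minus-control log2 differences, one column per lot.

    ``design`` needs columns ``sample``, ``lot``, ``arm`` with arm in
    {treated, control}; every lot must contribute exactly one sample per arm.
    """
    required = {"sample", "lot", "arm"}
    if not required.issubset(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    bad_arm = set(design["arm"]) - {"treated", "control"}
    if bad_arm:
        raise ValueError(f"unknown arm labels: {sorted(bad_arm)}")
    diffs = {}
    for lot, grp in design.groupby("lot", sort=True):
        arms = grp.set_index("arm")["sample"]
        if sorted(arms.index) != ["control", "treated"]:
            raise ValueError(
                f"lot {lot!r} must have exactly one treated and one control sample"
            )
        diffs[lot] = values[arms["treated"]] - values[arms["control"]]
    if len(diffs) < 2:
        raise ValueError("paired inference requires >= 2 lots")
    return pd.DataFrame(diffs, index=values.index)


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def fit_variance_prior(s2: np.ndarray, d: int) -> ModeratedTParams:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Works on z = log(s^2): under the hierarchical model z equals
    log(s0^2) plus independent log-chi-square terms with known digamma/
    trigamma moments, so matching the sample mean and variance of z gives
    closed-form (d0, s0^2).  Zero-variance probes are excluded from the fit.
    When the observed spread of z does not exceed the chi-square contribution,
    d0 is infinite and every probe gets the common variance exp(mean moment).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    z = np.log(pos)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        return ModeratedTParams(d0=np.inf, s0_sq=float(np.exp(emean)), d=d)
    d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
    s0_sq = float(
        np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return ModeratedTParams(d0=d0, s0_sq=s0_sq, d=d)


def paired_moderated_t(
    values: pd.DataFrame,
    design: pd.DataFrame,
    d0_override: float | None = None,
    s0_sq_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated paired t-test per probe.

    Returns a frame indexed by probe with ``logFC``, ``FC`` (2^logFC),
    ``t``, ``df_total``, ``p`` and ``p_adj`` (BH).  ``d0_override=0``
    recovers the ordinary paired t-test exactly.
    """
    diffs = paired_differences(values, design)
    n = diffs.shape[1]
    d = n - 1
    dmat = diffs.to_numpy()
    logfc = dmat.mean(axis=1)
    s2 = dmat.var(axis=1, ddof=1)

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(s0_sq_override) if s0_sq_override is not None else 1.0
    elif (s2 > 0).sum() < 2:
        # degenerate matrix (e.g. treated identical to control): no prior to
        # fit; fall back to the ordinary paired t, with t := 0 where s2 = 0
        d0, s0_sq = 0.0, 1.0
    else:
        params = fit_variance_prior(s2, d)
        d0 = params.d0
        s0_sq = params.s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = float(d0 + d)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(s2_post / n)
    t = np.where(np.isnan(t), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "FC": np.power(2.0, logfc),
            "t": t,
            "df_total": df_total,
            "p": p,
        },
        index=values.index,
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out.attrs["moderation"] = {"d0": d0, "s0_sq": s0_sq, "d": d, "n_pairs": n}
    return out


# ---------------------------------------------------------------------------
# multiplicity and calling
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def call_degs(
    result: pd.DataFrame,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Gate moderated-t results into {up, down, none} calls.

    Both gates are inclusive: up requires FC >= fc_up and adjusted p <=
    alpha; down requires FC <= fc_down and adjusted p <= alpha.
    """
    if fc_down >= fc_up:
        raise ValueError("fc_down must be below fc_up")
    out = result.copy()
    sig = out["p_adj"] <= alpha
    call = np.where(
        sig & (out["FC"] >= fc_up),
        "up",
        np.where(sig & (out["FC"] <= fc_down), "down", "none"),
    )
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(
    deg_ids: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation test per gene set.

    The p-value is the hypergeometric upper tail P(X >= overlap) with the
    universe as population, the gene set (intersected with the universe) as
    successes and the DEG list as draws.  BH adjustment runs across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    degs = set(deg_ids) & uni
    rows = []
    for name, members in gene_sets.items():
        in_uni = set(members) & uni
        overlap = len(in_uni & degs)
        # hypergeometric upper tail P(X >= overlap)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(in_uni), len(degs)))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(in_uni),
                "universe_size": len(uni),
                "deg_size": len(degs),
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] <= alpha
    return out


def superordinate_rollup(
    enrichment: pd.DataFrame,
    class_map: Mapping[str, str],
) -> pd.DataFrame:
    """Distribute significant enriched sets over six superordinate classes.

    ``class_map`` assigns set names to one of the six classes; unmapped sets
    fall into "others".  Returns counts and fractions per class (fractions
    are zero when nothing is significant).
    """
    bad = set(class_map.values()) - set(SUPERORDINATE_CLASSES)
    if bad:
        raise ValueError(f"unknown superordinate classes: {sorted(bad)}")
    sig = enrichment[enrichment.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
    counts = {c: 0 for c in SUPERORDINATE_CLASSES}
    for name in sig["set"]:
        counts[class_map.get(name, "others")] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "class": list(counts),
            "count": list(counts.values()),
            "fraction": [c / total if total else 0.0 for c in counts.values()],
        }
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples log2 TSV (first column = probe ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample/lot/arm design CSV."""
    return pd.read_csv(path)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> member ids...

    Duplicate set names raise, since a set mapped twice is ambiguous for the
    superordinate rollup.
    """
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene set {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return sets
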
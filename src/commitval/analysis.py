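"""Statistical summaries of pass evaluations: descriptive statistics,
rank-based comparisons, rank correlation, density profiling, and
team-level reports.

Operates on the evaluation table produced by
:func:`commitval.decision.evaluate_passes` (columns ``dom_dec`` /
``dom_alt`` etc.; see ``decision.EVALUATION_COLUMNS``).  Rows with an
undefined decision value are excluded from DV statistics only.  Raw
p-values are reported throughout; no multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VARIABLES",
    "SummaryReport",
    "TeamReport",
    "DensityProfile",
    "summarize",
    "rank_compare",
    "rank_correlation",
    "distribution_profile",
    "team_report",
]

#: (report name, decision column, alternative column); DV has no
#: alternative column (the alternative's DV is identically 1)
VARIABLES = [
    ("dominance", "dom_dec", "dom_alt"),
    ("influence", "inf_dec", "inf_alt"),
    ("risk", "risk_dec", "risk_alt"),
    ("expected_outcome", "eo_dec", "eo_alt"),
    ("decision_value", "dv", None),
    ("distance", "dist_dec", "dist_alt"),
]


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return (float("nan"), float("nan"))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return (float(np.mean(values)), sd)


@dataclass
class SummaryReport:
    """Mean +/- SD per variable for decisions and alternatives."""

    table: pd.DataFrame             # index: variable; mean/sd x dec/alt
    n_passes: int
    n_matches: int
    n_dv_defined: int
    kicks_per_match_mean: float
    kicks_per_match_sd: float

    def to_dict(self) -> dict:
        return {
            "n_passes": self.n_passes,
            "n_matches": self.n_matches,
            "n_dv_defined": self.n_dv_defined,
            "kicks_per_match_mean": self.kicks_per_match_mean,
            "kicks_per_match_sd": self.kicks_per_match_sd,
            "variables": self.table.to_dict(orient="index"),
        }


def summarize(evaluations: pd.DataFrame) -> SummaryReport:
    """Descriptive statistics (mean +/- SD) over an evaluation table.

    Requires at least 2 rows.  Undefined DVs (NaN) are dropped from the
    decision-value row only; kicks per match come from per-``match_id``
    counts.
    """
    if len(evaluations) < 2:
        raise ValueError("need at least 2 evaluations to summarize")
    rows = {}
    for name, dec_col, alt_col in VARIABLES:
        mean_dec, sd_dec = _mean_sd(evaluations[dec_col].to_numpy())
        if alt_col is not None:
            mean_alt, sd_alt = _mean_sd(evaluations[alt_col].to_numpy())
        else:
            mean_alt, sd_alt = (float("nan"), float("nan"))
        rows[name] = {
            "mean_dec": mean_dec,
            "sd_dec": sd_dec,
            "mean_alt": mean_alt,
            "sd_alt": sd_alt,
        }
    per_match = evaluations.groupby("match_id").size().to_numpy(dtype=float)
    kpm_mean, kpm_sd = _mean_sd(per_match)
    return SummaryReport(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        n_passes=len(evaluations),
        n_matches=int(len(per_match)),
        n_dv_defined=int(evaluations["dv"].notna().sum()),
        kicks_per_match_mean=kpm_mean,
        kicks_per_match_sd=kpm_sd,
    )


def rank_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U computed for ``sample_a``.  Small tie-free
    samples use the exact null distribution; otherwise the tie-corrected
    normal approximation is used.  Two constant, identical samples return
    ``p = 1`` by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return (a.size * b.size / 2.0, 1.0)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return (float(res.statistic), float(res.pvalue))


def rank_correlation(x, y) -> float:
    """Spearman's rho with average ranks for ties; NaN when a rank
    variance is zero (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class DensityProfile:
    """1-D Gaussian-kernel density curve with its maxima."""

    grid: np.ndarray
    density: np.ndarray
    peak: float                     # location of the global maximum
    local_maxima: list[float]       # includes the global peak

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.grid, "density": self.density})


def distribution_profile(
    values,
    bandwidth: float | None = None,
    grid_size: int = 512,
    extend: float = 3.0,
) -> DensityProfile:
    """Fit a 1-D Gaussian KDE and report its global and local maxima.

    ``bandwidth`` is in data units; when omitted, Scott's plug-in rule is
    used.  A degenerate (zero-spread) sample returns a point mass at the
    shared value.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 5:
        raise ValueError("need at least 5 values for a density profile")
    if np.ptp(values) == 0.0:
        v = float(values[0])
        return DensityProfile(
            grid=np.array([v]), density=np.array([1.0]), peak=v, local_maxima=[v]
        )
    sd = float(np.std(values, ddof=1))
    bw_method = None if bandwidth is None else bandwidth / sd
    kde = stats.gaussian_kde(values, bw_method=bw_method)
    bw_abs = float(kde.factor) * sd
    grid = np.linspace(values.min() - extend * bw_abs, values.max() + extend * bw_abs, grid_size)
    density = kde(grid)
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    maxima_idx = list(np.nonzero(interior)[0] + 1)
    if density[0] > density[1]:
        maxima_idx.insert(0, 0)
    if density[-1] > density[-2]:
        maxima_idx.append(len(density) - 1)
    peak = float(grid[int(np.argmax(density))])
    return DensityProfile(
        grid=grid,
        density=density,
        peak=peak,
        local_maxima=[float(grid[i]) for i in maxima_idx],
    )


@dataclass
class TeamReport:
    """Per-team summaries, per-variable rank tests, and within-team
    per-player mean/SD distributions."""

    team_a: str
    team_b: str
    summary_a: pd.DataFrame
    summary_b: pd.DataFrame
    tests: pd.DataFrame             # index: variable; columns: U, p, n_a, n_b
    player_means: dict              # team -> variable -> np.ndarray
    player_sds: dict

    def to_dict(self) -> dict:
        return {
            "team_a": self.team_a,
            "team_b": self.team_b,
            "summary_a": self.summary_a.to_dict(orient="index"),
            "summary_b": self.summary_b.to_dict(orient="index"),
            "tests": self.tests.to_dict(orient="index"),
        }


def team_report(evaluations: pd.DataFrame, team_a: str, team_b: str) -> TeamReport:
    """Compare decision-making characteristics of two teams.

    Uses the decision-side columns of each variable, split by the kicking
    team; per-player distributions are grouped by kicker id.
    """
    frames = {}
    for team in (team_a, team_b):
        sub = evaluations[evaluations["kicker_team"] == team]
        if len(sub) == 0:
            raise ValueError(f"no evaluations for team {team!r}")
        frames[team] = sub

    summaries = {}
    tests = {}
    player_means: dict = {team_a: {}, team_b: {}}
    player_sds: dict = {team_a: {}, team_b: {}}
    for name, dec_col, _alt in VARIABLES:
        rows = {}
        for team in (team_a, team_b):
            mean, sd = _mean_sd(frames[team][dec_col].to_numpy())
            rows[team] = {"mean": mean, "sd": sd}
            grouped = frames[team].groupby("kicker_id")[dec_col]
            player_means[team][name] = grouped.mean().to_numpy()
            player_sds[team][name] = grouped.std(ddof=1).to_numpy()
        u, p = rank_compare(
            frames[team_a][dec_col].to_numpy(), frames[team_b][dec_col].to_numpy()
        )
        tests[name] = {
            "U": u,
            "p": p,
            "n_a": int(frames[team_a][dec_col].notna().sum()),
            "n_b": int(frames[team_b][dec_col].notna().sum()),
        }
        summaries.setdefault("rows", {})[name] = rows

    summary_a = pd.DataFrame.from_dict(
        {k: v[team_a] for k, v in summaries["rows"].items()}, orient="index"
    )
    summary_b = pd.DataFrame.from_dict(
        {k: v[team_b] for k, v in summaries["rows"].items()}, orient="index"
    )
    return TeamReport(
        team_a=team_a,
        team_b=team_b,
        summary_a=summary_a,
        summary_b=summary_b,
        tests=pd.DataFrame.from_dict(tests, orient="index"),
        player_means=player_means,
        player_sds=player_sds,
    )
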
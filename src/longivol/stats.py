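"""Atrophy-rate statistics.

The atom of every analysis is one percentage-volume-change (PVC) record:

    PVC = (V_FU − V_BL) / V_BL × 100        (negative = atrophy)

measured for one subject, one scan replicate (A or B of a back-to-back
pair), one side (left/right) and one method. On tables of such records this
module implements the evaluation statistics of a longitudinal volumetry
study:

* the ±25% plausibility exclusion (flagging, never deleting);
* left/right averaging to subject-level atrophy rates;
* D_Ave, the RMS difference between paired PVC measurements, used both for
  A-vs-B test–retest reproducibility and for between-method agreement;
* group ANOVA (CTRL/MCI/AD) with Tukey HSD post-hoc tests;
* Cohen's d effect size and the normal-approximation sample size
  N = 2(z_{α/2} + z_{1−β})² / d² per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "PVC_COLUMNS",
    "CohortTable",
    "AnovaResult",
    "PowerResult",
    "pvc",
    "apply_exclusion",
    "subject_pvc",
    "d_ave_scans",
    "d_ave_methods",
    "distance_matrix",
    "group_anova",
    "power_analysis",
]

#: Canonical CSV schema for PVC records (UTF-8, "." decimal separator).
PVC_COLUMNS = [
    "subject",
    "group",
    "scan",
    "side",
    "method",
    "v_bl",
    "v_fu",
    "pvc",
    "excluded",
    "exclude_reason",
]

DEFAULT_THRESHOLD = 25.0


def pvc(v_bl: float, v_fu: float) -> float:
    """Percentage volume change (V_FU − V_BL)/V_BL × 100; atrophy is negative."""
    if v_bl <= 0:
        raise ValueError(f"baseline volume must be positive, got {v_bl}")
    return (v_fu - v_bl) / v_bl * 100.0


@dataclass
class CohortTable:
    """A collection of PVC records with provenance and exclusion flags.

    ``df`` holds one row per (subject, scan, side, method) with the columns
    of :data:`PVC_COLUMNS`; that key must be unique.
    """

    df: pd.DataFrame
    threshold: float = DEFAULT_THRESHOLD
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("subject", "group", "scan", "side", "method", "pvc")
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        df = self.df.copy()
        if "excluded" not in df.columns:
            df["excluded"] = False
        if "exclude_reason" not in df.columns:
            df["exclude_reason"] = ""
        key = ["subject", "scan", "side", "method"]
        if df.duplicated(subset=key).any():
            raise ValueError("duplicate (subject, scan, side, method) records")
        if "v_bl" in df.columns and (pd.to_numeric(df["v_bl"]) <= 0).any():
            raise ValueError("baseline volumes must be positive")
        self.df = df

    @property
    def methods(self) -> list[str]:
        return sorted(self.df["method"].unique())

    def for_method(self, method: str) -> "CohortTable":
        sub = self.df[self.df["method"] == method].copy()
        return CohortTable(sub, threshold=self.threshold,
                           provenance=dict(self.provenance))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, threshold: float = DEFAULT_THRESHOLD) -> "CohortTable":
        df = pd.read_csv(path)
        if "excluded" in df.columns:
            df["excluded"] = df["excluded"].astype(bool)
        if "exclude_reason" in df.columns:
            df["exclude_reason"] = df["exclude_reason"].fillna("")
        return cls(df, threshold=threshold)


def apply_exclusion(table: CohortTable, threshold: float = DEFAULT_THRESHOLD) -> CohortTable:
    """Flag records with |PVC| strictly greater than ``threshold`` percent.

    Implausibly large volume change (beyond ±25% in one interval) indicates a
    failed segmentation or registration. Records are flagged, never deleted,
    so each analysis can apply its own mask and the exclusions stay
    auditable. Flagged counts per group and scan are logged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    df = table.df.copy()
    mask = df["pvc"].abs() > threshold
    df["excluded"] = mask
    df["exclude_reason"] = np.where(mask, f"|pvc|>{threshold:g}", "")
    if mask.any():
        counts = (
            df[mask].groupby(["method", "group", "scan"], observed=True)
            .size().to_dict()
        )
        log.warning("flagged %d of %d records beyond ±%g%%: %s",
                    int(mask.sum()), len(df), threshold, counts)
    return CohortTable(df, threshold=threshold, provenance=dict(table.provenance))


def subject_pvc(table: CohortTable) -> pd.DataFrame:
    """Average left and right PVC into per-(subject, scan) atrophy rates.

    A subject-scan contributes only when both sides are present and
    unflagged; otherwise it is omitted and the omission logged. Returns a
    tidy frame with columns subject, group, scan, method, pvc.
    """
    df = table.df
    usable = df[~df["excluded"]]
    rows = []
    n_dropped = 0
    for (method, subject, scan), grp in usable.groupby(
        ["method", "subject", "scan"], observed=True, sort=True
    ):
        sides = set(grp["side"])
        if sides >= {"L", "R"}:
            rows.append({
                "subject": subject,
                "group": grp["group"].iloc[0],
                "scan": scan,
                "method": method,
                "pvc": grp[grp["side"].isin(["L", "R"])]["pvc"].mean(),
            })
        else:
            n_dropped += 1
    if n_dropped:
        log.warning("subject_pvc: omitted %d subject-scans lacking both "
                    "unflagged sides", n_dropped)
    return pd.DataFrame(rows, columns=["subject", "group", "scan", "method", "pvc"])


def _rms(diff: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(diff))))


def d_ave_scans(pvc_a: np.ndarray, pvc_b: np.ndarray) -> float:
    """Test–retest distance: RMS difference of subject-paired A and B PVCs (%).

    Back-to-back scans are seconds apart, so the true change between them is
    zero and D_Ave measures pure method noise.
    """
    pvc_a = np.asarray(pvc_a, dtype=float)
    pvc_b = np.asarray(pvc_b, dtype=float)
    if pvc_a.shape != pvc_b.shape:
        raise ValueError("A and B PVC vectors must pair up one-to-one")
    if pvc_a.size == 0:
        raise ValueError("need at least one pair")
    return _rms(pvc_a - pvc_b)


def d_ave_methods(pvc_m1: np.ndarray, pvc_m2: np.ndarray) -> float:
    """Between-method agreement: RMS difference over the pooled A+B records (%).

    Same statistic as :func:`d_ave_scans` applied across methods; symmetric
    in its arguments and zero iff the methods agree exactly.
    """
    pvc_m1 = np.asarray(pvc_m1, dtype=float)
    pvc_m2 = np.asarray(pvc_m2, dtype=float)
    if pvc_m1.shape != pvc_m2.shape:
        raise ValueError("methods must be compared on the same record set")
    if pvc_m1.size == 0:
        raise ValueError("need at least one record")
    return _rms(pvc_m1 - pvc_m2)


def scan_pairs(subject_df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Align per-subject A and B PVCs from a subject-level table (one method)."""
    wide = subject_df.pivot_table(index="subject", columns="scan", values="pvc")
    wide = wide.dropna(subset=["A", "B"])
    return wide["A"].to_numpy(), wide["B"].to_numpy()


def distance_matrix(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise D_Ave between methods over their common subject-scan records.

    ``tables`` maps method label → subject-level frame (columns subject,
    scan, pvc). Returns a symmetric DataFrame with zero diagonal, ordered by
    the input keys.
    """
    if len(tables) < 2:
        raise ValueError("need at least two methods")
    methods = list(tables)
    aligned = {}
    for m, df in tables.items():
        aligned[m] = df.set_index(["subject", "scan"])["pvc"]
    out = pd.DataFrame(0.0, index=methods, columns=methods)
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            joined = pd.concat([aligned[m1], aligned[m2]], axis=1, join="inner")
            d = d_ave_methods(joined.iloc[:, 0].to_numpy(),
                              joined.iloc[:, 1].to_numpy())
            out.loc[m1, m2] = out.loc[m2, m1] = d
    return out


def plot_distance_matrix(matrix: pd.DataFrame, path) -> None:
    """Render the method-agreement matrix as an annotated heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.7 * len(matrix), 1.0 + 0.7 * len(matrix)))
    im = ax.imshow(matrix.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix)), matrix.index)
    for i in range(len(matrix)):
        for j in range(len(matrix)):
            ax.text(j, i, f"{matrix.iat[i, j]:.2f}", ha="center", va="center",
                    color="white", fontsize=8)
    fig.colorbar(im, ax=ax, label="D_Ave (%)")
    ax.set_title("Between-method atrophy-rate distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class AnovaResult:
    """Group ANOVA summary with Tukey-HSD pairwise post-hoc p-values."""

    F: float
    df_between: int
    df_error: int
    p_value: float
    posthoc: pd.DataFrame  # columns: group1, group2, meandiff, p_adj
    mode: str = "pooled"

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "F": self.F,
            "df_between": self.df_between,
            "df_error": self.df_error,
            "p_value": self.p_value,
            "tukey": self.posthoc.to_dict(orient="records"),
        }


def _tukey(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if np.ptp(values) == 0:  # degenerate: no variation anywhere
        pairs = list(combinations(sorted(set(map(str, groups))), 2))
        return pd.DataFrame({
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": 0.0,
            "p_adj": 1.0,
        })
    res = pairwise_tukeyhsd(values, groups)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    return pd.DataFrame({
        "group1": frame["group1"].astype(str),
        "group2": frame["group2"].astype(str),
        "meandiff": frame["meandiff"].astype(float),
        "p_adj": frame["p-adj"].astype(float),
    })


def group_anova(subject_df: pd.DataFrame, mode: str = "pooled") -> AnovaResult:
    """Compare diagnostic-group atrophy rates by ANOVA with Tukey HSD.

    Parameters
    ----------
    subject_df
        Subject-level PVCs (columns subject, group, scan, pvc) for a single
        method, typically from :func:`subject_pvc`.
    mode
        ``"pooled"`` treats the A and B replicates of each subject as
        separate observations in a one-way ANOVA; with 80 subjects × 2
        scans in 3 groups this yields the df pattern F(2, 157). ``"mixed"``
        fits the principled group × scan mixed design (scan as the
        within-subject factor) and reports the between-group effect.

    Tukey HSD adjusted pairwise p-values are computed in both modes — on the
    pooled observations for ``pooled``, on subject means for ``mixed``.
    """
    counts = subject_df.groupby("group", observed=True)["pvc"].size()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 observations")
    if mode == "pooled":
        grouped = [g["pvc"].to_numpy() for _, g in
                   subject_df.groupby("group", observed=True)]
        df_between = len(grouped) - 1
        df_error = len(subject_df) - len(grouped)
        grand = subject_df["pvc"].mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in grouped)
        if ss_between == 0:  # no between-group variation at all
            F, p = 0.0, 1.0
        else:
            F, p = sps.f_oneway(*grouped)
        posthoc = _tukey(subject_df["pvc"].to_numpy(),
                         subject_df["group"].to_numpy())
        return AnovaResult(float(F), df_between, df_error, float(p),
                           posthoc, mode="pooled")
    if mode == "mixed":
        import pingouin as pg

        aov = pg.mixed_anova(data=subject_df, dv="pvc", within="scan",
                             subject="subject", between="group")
        aov = aov.rename(columns={"p-unc": "p_unc"})
        row = aov[aov["Source"] == "group"].iloc[0]
        means = (subject_df.groupby(["subject", "group"], observed=True)["pvc"]
                 .mean().reset_index())
        posthoc = _tukey(means["pvc"].to_numpy(), means["group"].to_numpy())
        return AnovaResult(float(row["F"]), int(row["DF1"]), int(row["DF2"]),
                           float(row["p_unc"]), posthoc, mode="mixed")
    raise ValueError(f"unknown ANOVA mode {mode!r}")


@dataclass
class PowerResult:
    """Effect size and required per-group sample size for a two-group contrast."""

    mu1: float
    mu2: float
    sigma_pooled: float
    cohen_d: float
    n_per_group: int
    alpha: float
    power: float

    def as_dict(self) -> dict:
        return {
            "mu1": self.mu1, "mu2": self.mu2,
            "sigma_pooled": self.sigma_pooled, "cohen_d": self.cohen_d,
            "n_per_group": self.n_per_group,
            "alpha": self.alpha, "power": self.power,
        }


def power_analysis(
    mu1: float, sigma1: float, mu2: float, sigma2: float,
    alpha: float = 0.05, power: float = 0.80,
) -> PowerResult:
    """Normal-approximation sample size to detect a group PVC difference.

        N = 2 (z_{α/2} + z_{1−β})² / d²,   d = |μ₂ − μ₁| / σ_pooled

    with σ_pooled the unweighted root-mean of the two group variances,
    σ_pooled = sqrt((σ₁² + σ₂²)/2), a two-sided test at level ``alpha`` and
    target ``power``. At the defaults the normal quantiles are
    z_{α/2} = 1.96 and z_{1−β} = 0.8416. N is rounded to the nearest
    integer and is per group.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("group SDs must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if mu1 == mu2:
        raise ValueError("zero effect, infinite N")
    sigma_pooled = float(np.sqrt((sigma1**2 + sigma2**2) / 2.0))
    d = abs(mu2 - mu1) / sigma_pooled
    z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
    n = 2 * z**2 / d**2
    n_per_group = int(np.floor(n + 0.5))
    return PowerResult(mu1=mu1, mu2=mu2, sigma_pooled=sigma_pooled,
                       cohen_d=float(d), n_per_group=n_per_group,
                       alpha=alpha, power=power)
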
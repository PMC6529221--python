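"""The behavioural screen's statistics chain.

Per-line preference indices (one PI per group-of-20 experiment) are screened
against the empty split-GAL4 control: a Levene test checks homoskedasticity,
a Kruskal-Wallis rank-sum test is followed by Dunn's post-hoc comparisons of
each line against the control, and the resulting p-values are adjusted by
Benjamini-Hochberg (screens, controlling the false discovery rate at 10%,
with significance declared at adjusted p < 0.05) or by Bonferroni
(replication experiments).  All tests are two-sided — the screen is equally
interested in attraction and aversion.

Dunn's z for treatment i against control 0 uses pooled mid-ranks:

    z_i = (Rbar_i - Rbar_0) / sqrt[(N(N+1)/12 - T) (1/n_i + 1/n_0)]

with the tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: FDR level the screen controls, and the adjusted-p significance cut
FDR_LEVEL = 0.10
ALPHA = 0.05


def coverage_percent(n_identified: int, n_known: int) -> float:
    """Percent coverage of a known cell-type catalogue, e.g. 63 of the ~165
    core lateral-horn cell types."""
    if n_known <= 0:
        raise ValueError("n_known must be positive")
    return 100.0 * n_identified / n_known


def levene_check(groups: list, center: str = "median") -> tuple[float, float]:
    """Levene/Brown-Forsythe test for equal spread across groups.

    ``center='median'`` (default) is the Brown-Forsythe variant — the robust
    choice for skewed behavioural scores; ``center='mean'`` gives the
    classical Levene statistic (the one-way ANOVA F on absolute deviations
    from the group means).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    # groups that are all constant have zero spread deviations everywhere;
    # the F ratio degenerates to 0/0, which we define as 0 (perfectly equal
    # spread) rather than propagate a NaN
    if all(np.ptp(g) == 0 for g in arrays):
        return 0.0, 1.0
    stat, p = sps.levene(*arrays, center=center)
    return float(stat), float(p)


@dataclass
class DunnResult:
    h_statistic: float
    kruskal_p: float
    z: np.ndarray  # one per treatment, vs control
    p: np.ndarray  # two-sided, unadjusted


def kruskal_dunn_vs_control(control, treatments: list) -> DunnResult:
    """Kruskal-Wallis over all groups, then Dunn's z for each treatment
    against the control on the pooled ranks, with tie-corrected variance."""
    groups = [np.asarray(control, dtype=float)] + [
        np.asarray(t, dtype=float) for t in treatments
    ]
    for g in groups:
        if len(g) < 2:
            raise ValueError("each sample needs n >= 2")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("all observations are tied: ranks carry no information")
    h, kw_p = sps.kruskal(*groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    # tie correction: sum over tie groups of (t^3 - t) / (12 (N - 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    base_var = n * (n + 1) / 12.0 - tie_term
    n0 = len(groups[0])
    z = np.array(
        [
            (mean_ranks[i] - mean_ranks[0])
            / np.sqrt(base_var * (1.0 / len(groups[i]) + 1.0 / n0))
            for i in range(1, len(groups))
        ]
    )
    p = 2.0 * sps.norm.sf(np.abs(z))
    return DunnResult(h_statistic=float(h), kruskal_p=float(kw_p), z=z, p=np.minimum(p, 1.0))


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = _check_p(p)
    return multipletests(p, method="fdr_bh")[1]


def adjust_bonferroni(p) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p)."""
    p = _check_p(p)
    return np.minimum(1.0, len(p) * p)


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("expected a non-empty 1D vector of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def screen(
    df: pd.DataFrame,
    control: str = "empty_split",
    adjust: str = "fdr",
    alpha: float = ALPHA,
    fdr_level: float = FDR_LEVEL,
    value_col: str = "pi",
    line_col: str = "line_id",
) -> pd.DataFrame:
    """Run the full screening chain on a tidy per-replicate table.

    ``df`` holds one row per experiment with the line identifier and its PI
    (or any other per-replicate metric).  Returns one row per non-control
    line with the raw Dunn p, the adjusted p (``adjust`` is ``"fdr"`` for
    the Benjamini-Hochberg screen or ``"bonferroni"`` for replications) and
    the significance flag at adjusted p < ``alpha``; the FDR level the
    screen controls is carried alongside.
    """
    if adjust not in ("fdr", "bonferroni"):
        raise ValueError(f"adjust must be 'fdr' or 'bonferroni', got {adjust!r}")
    lines = [l for l in df[line_col].unique() if l != control]
    if control not in set(df[line_col]):
        raise ValueError(f"control line {control!r} not present")
    control_vals = df.loc[df[line_col] == control, value_col].to_numpy()
    treatment_vals = [df.loc[df[line_col] == l, value_col].to_numpy() for l in lines]
    dunn = kruskal_dunn_vs_control(control_vals, treatment_vals)
    adjusted = adjust_fdr(dunn.p) if adjust == "fdr" else adjust_bonferroni(dunn.p)
    return pd.DataFrame(
        {
            "line_id": lines,
            "n": [len(v) for v in treatment_vals],
            "z": dunn.z,
            "raw_p": dunn.p,
            "adjusted_p": adjusted,
            "method": "dunn_fdr" if adjust == "fdr" else "dunn_bonferroni",
            "significant": adjusted < alpha,
            "fdr_level": fdr_level,
        }
    )
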
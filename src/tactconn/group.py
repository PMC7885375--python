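"""Group-level statistics on network indices and node degrees.

Each index is compared between the two stimulated forearms with a
paired t-test after a Shapiro–Wilk normality screen on the paired
differences; when the screen fails (p <= 0.05) a Wilcoxon signed-rank
p is reported alongside with a warning. Effect size is Cohen's d_z
(mean difference over SD of differences); the common-language effect
size (fraction of subjects whose difference shares the mean's sign)
is reported as a secondary, explicitly labelled estimator. Node-level
(per-channel) comparisons are corrected with Benjamini–Hochberg FDR,
separately per index family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import SFCResult, hl_degree_display, topography_summary
from .montage import Montage

__all__ = [
    "PairedComparison",
    "shapiro_screen",
    "paired_compare",
    "node_level_fdr",
    "hl_report",
]

log = logging.getLogger(__name__)


def shapiro_screen(values: np.ndarray) -> float:
    """Shapiro–Wilk p of paired differences (normality screen)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("constant input: normality test undefined")
    return float(stats.shapiro(values).pvalue)


@dataclass
class PairedComparison:
    """Paired t-test between two within-subject conditions."""

    n: int
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    t: float
    p: float
    df: int
    effect_size_dz: float
    effect_size_common_language: float
    shapiro_p: float
    wilcoxon_p: float | None  # reported when the normality screen fails

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n", "mean_a", "mean_b", "t", "p", "df",
            "effect_size_dz", "effect_size_common_language", "shapiro_p",
        )}
        d["ci_a"] = list(self.ci_a)
        d["ci_b"] = list(self.ci_b)
        d["wilcoxon_p"] = self.wilcoxon_p
        return d


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = len(values)
    m = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / np.sqrt(n))
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * sem
    return (m - half, m + half)


def paired_compare(a: np.ndarray, b: np.ndarray) -> PairedComparison:
    """Two-sided paired t-test of per-subject values ``a`` vs ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length per-subject vectors")
    n = len(a)
    if n < 2:
        raise ValueError("paired comparison needs at least 2 subjects")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() != 0:
            raise ValueError(
                "zero variance of nonzero paired differences; t infinite"
            )
        t, p, dz = 0.0, 1.0, 0.0  # a == b exactly: a well-defined null
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2 * stats.t.sf(abs(t), df=n - 1))
        dz = float(d.mean() / sd)
    cles = float(np.mean(np.sign(d) == np.sign(d.mean()))) if d.mean() != 0 else 0.5
    shapiro_p = shapiro_screen(d) if n >= 3 and sd > 0 else float("nan")
    wilcoxon_p = None
    if n >= 3 and shapiro_p <= 0.05:
        log.warning(
            "paired differences fail the normality screen (Shapiro p=%.3g); "
            "reporting Wilcoxon signed-rank alongside", shapiro_p,
        )
        wilcoxon_p = float(stats.wilcoxon(a, b).pvalue)
    return PairedComparison(
        n=n,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ci_a=_t_ci(a),
        ci_b=_t_ci(b),
        t=t,
        p=p,
        df=n - 1,
        effect_size_dz=dz,
        effect_size_common_language=cles,
        shapiro_p=shapiro_p,
        wilcoxon_p=wilcoxon_p,
    )


def node_level_fdr(
    t_values: np.ndarray,
    p_values: np.ndarray,
    channel_names: tuple[str, ...],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Benjamini–Hochberg step-up across channels.

    Returns one row per channel: t, raw p, adjusted p, significance flag
    and the sign of the effect (for topographic display).
    """
    t_values = np.asarray(t_values, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    if len(t_values) != len(channel_names) or len(p_values) != len(channel_names):
        raise ValueError("t/p vectors must match channel count")
    reject, p_adj, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({
        "channel": list(channel_names),
        "t": t_values,
        "p": p_values,
        "p_fdr": p_adj,
        "significant": reject,
        "sign": np.sign(t_values).astype(int),
    })


def hl_report(
    sfc_results: dict[tuple[str, str], SFCResult | None],
    montage: Montage,
) -> pd.DataFrame:
    """HL degree and mean SFC intensities per (group, stimulated limb).

    ``sfc_results`` maps (group, stimulated_limb) to an
    :class:`~tactconn.cluster.SFCResult`; a missing or empty cell yields
    a row of nulls with a warning rather than an error.
    """
    rows = []
    for (grp, limb), sfc in sorted(sfc_results.items()):
        row = {"group": grp, "limb": limb}
        try:
            if sfc is None:
                raise ValueError("missing SFC result")
            summ = topography_summary(sfc, montage, stimulated_side=limb)
            row.update(
                n_total=summ["n_total"],
                n_contra=summ["n_contra"],
                hl_degree=summ["hl_degree"],
                hl_degree_display=hl_degree_display(summ["hl_degree"]),
                mean_intensity_contra=summ["mean_intensity_contra"],
                mean_intensity_ipsi=summ["mean_intensity_ipsi"],
            )
        except ValueError as exc:
            log.warning("no SFC for %s/%s: %s", grp, limb, exc)
            row.update(
                n_total=None, n_contra=None, hl_degree=None,
                hl_degree_display=None, mean_intensity_contra=None,
                mean_intensity_ipsi=None,
            )
        rows.append(row)
    return pd.DataFrame(rows)
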
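"""Study-level statistics.

Per-retina summaries (density per analysed pixel, morphotype
percentages overall and within the PA/nPA compartments), Bland-Altman
agreement between counting variants, and group comparisons
(Kruskal-Wallis, two-tailed Mann-Whitney, two-way ANOVA with
Sidak-corrected multiple comparisons).

Densities are expressed per analysed (artefact-excluded) pixel and
morphotype counts as percentages of each retina's total, so retinas
of different analysed area are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .morphotype import LABEL_ORDER

_LABELS = [label.value for label in LABEL_ORDER]


@dataclass
class RetinaSummary:
    retina_id: str
    group: str
    total_cells: int
    analysed_px: int
    density: float  # cells per analysed pixel
    pct_by_morphotype: dict[str, float]
    pa_pct_by_morphotype: dict[str, float]
    npa_pct_by_morphotype: dict[str, float]

    def as_row(self) -> pd.Series:
        row = {
            "retina_id": self.retina_id,
            "group": self.group,
            "total_cells": self.total_cells,
            "analysed_px": self.analysed_px,
            "density": self.density,
        }
        for k, v in self.pct_by_morphotype.items():
            row[f"pct_{k}"] = v
        for k, v in self.pa_pct_by_morphotype.items():
            row[f"pa_pct_{k}"] = v
        for k, v in self.npa_pct_by_morphotype.items():
            row[f"npa_pct_{k}"] = v
        return pd.Series(row)


@dataclass
class AgreementResult:
    """Bland-Altman agreement between two paired count series."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


def _percentages(labels: pd.Series) -> dict[str, float]:
    n = len(labels)
    if n == 0:
        return {k: 0.0 for k in _LABELS}
    counts = labels.value_counts()
    return {k: 100.0 * counts.get(k, 0) / n for k in _LABELS}


def summarise_retina(
    labels: pd.Series,
    pa_flags: pd.Series,
    analysed_px: int,
    retina_id: str = "",
    group: str = "",
) -> RetinaSummary:
    """Density and morphotype percentage summary of one retina.

    ``labels`` holds a morphotype string per counted cell, ``pa_flags``
    a boolean per cell; PA/nPA percentages are computed within the
    respective subsets.  Zero analysed pixels is an error; zero cells
    yields zero density and zero percentages with a warning.
    """
    if analysed_px <= 0:
        raise ValueError("analysed_px must be > 0")
    labels = pd.Series(labels).reset_index(drop=True)
    pa_flags = pd.Series(pa_flags).reset_index(drop=True).astype(bool)
    if len(labels) != len(pa_flags):
        raise ValueError("labels and pa_flags must have equal length")
    n = len(labels)
    if n == 0:
        warnings.warn("retina has zero cells; percentages set to 0", stacklevel=2)
    return RetinaSummary(
        retina_id=retina_id,
        group=group,
        total_cells=n,
        analysed_px=int(analysed_px),
        density=n / analysed_px,
        pct_by_morphotype=_percentages(labels),
        pa_pct_by_morphotype=_percentages(labels[pa_flags.values]),
        npa_pct_by_morphotype=_percentages(labels[~pa_flags.values]),
    )


def bland_altman(a, b) -> AgreementResult:
    """Limits-of-agreement analysis of two paired measurement series.

    Differences are ``a - b`` pairwise; bias is their mean, the limits
    of agreement are bias +/- 1.96 sample standard deviations (ddof 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    diffs = a - b
    means = (a + b) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, means, diffs)


def group_compare(
    values,
    groups,
    test: str = "kruskal_wallis",
    factor2=None,
    alpha: float = 0.05,
) -> dict:
    """Group comparison via standard statistical routines.

    ``test`` is one of ``kruskal_wallis``, ``mann_whitney_two_tailed``
    (exactly two groups) or ``anova2_multcomp`` (two-way ANOVA on
    ``groups`` x ``factor2`` with Sidak-corrected pairwise comparisons
    of ``groups``).  Returns a dict with the statistic, p-value and,
    where applicable, a pairwise comparison table.  Significance is
    judged at ``alpha`` (default 0.05).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups).tolist())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in names]

    if test == "kruskal_wallis":
        stat, p = stats.kruskal(*samples)
        return {"test": test, "statistic": float(stat), "p_value": float(p),
                "significant": bool(p < alpha)}
    if test == "mann_whitney_two_tailed":
        if len(names) != 2:
            raise ValueError("Mann-Whitney requires exactly 2 groups")
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return {"test": test, "statistic": float(stat), "p_value": float(p),
                "significant": bool(p < alpha)}
    if test == "anova2_multcomp":
        if factor2 is None:
            raise ValueError("anova2_multcomp requires factor2")
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = pd.DataFrame(
            {"value": values, "g1": groups, "g2": np.asarray(factor2)}
        )
        model = ols("value ~ C(g1) + C(g2) + C(g1):C(g2)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        # Sidak-corrected pairwise comparisons on the primary factor
        pairs = []
        raw = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a = df.loc[df.g1 == names[i], "value"]
                b = df.loc[df.g1 == names[j], "value"]
                t, p = stats.ttest_ind(a, b)
                pairs.append((names[i], names[j], float(t)))
                raw.append(float(p))
        m = len(raw)
        adj = [1.0 - (1.0 - p) ** m for p in raw]
        pairwise = pd.DataFrame(
            {
                "a": [p[0] for p in pairs],
                "b": [p[1] for p in pairs],
                "t": [p[2] for p in pairs],
                "p_raw": raw,
                "p_sidak": adj,
                "significant": [p < alpha for p in adj],
            }
        )
        return {
            "test": test,
            "anova_table": table,
            "p_value": float(table["PR(>F)"].iloc[0]),
            "pairwise": pairwise,
        }
    raise ValueError(f"unknown test {test!r}")


def summaries_to_frame(summaries: list[RetinaSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])


def bland_altman_plot(result: AgreementResult, path, title: str = "") -> None:
    """Write a Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=12, alpha=0.7)
    ax.axhline(result.bias, color="blue", ls=":", label=f"bias {result.bias:.2f}")
    for v in (result.loa_low, result.loa_high):
        ax.axhline(v, color="red", ls=":")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
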
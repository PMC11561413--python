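"""Inferential statistics for the balanced two-factor RCBD screen.

Implements, from explicit balanced-design sums of squares:

* two-factor randomized-complete-block ANOVA (block = replicate column set,
  factors = treatment and hybrid, plus their interaction) with star-coded
  p-values;
* Fisher's protected LSD mean separation with compact letter display;
* within-treatment Pearson correlation matrices with the star legend used
  for trait-correlation tables (* for p < 0.01, ** for p < 0.001), and a
  combined drought-above / control-below square report.

Only balanced data (every hybrid x treatment cell filled with the same
number of replicates, each replicate id complete) is supported; p-values
come from the F and t distributions via scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trait_model import (
    DesignSpec,
    ObservationTable,
    TraitDefinition,
    ValidationError,
)

__all__ = [
    "AnovaTable",
    "CorrelationMatrix",
    "LsdResult",
    "rcbd_anova",
    "star_code",
    "corr_star_code",
    "fisher_lsd",
    "pearson_matrix",
    "combined_matrix_report",
]

ANOVA_SOURCES = ["block", "treatment", "hybrid", "treatment:hybrid", "error", "total"]


def star_code(p: float) -> str:
    """Three-tier significance stars (strict thresholds 0.001 / 0.01 / 0.05)."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def corr_star_code(p: float) -> str:
    """Correlation-table legend: ``*`` = p < 0.01, ``**`` = p < 0.001."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "**"
    if p < 0.01:
        return "*"
    return "NS"


@dataclass(frozen=True)
class AnovaTable:
    """Source-wise decomposition for one trait (SS, df, MS, F, p, stars)."""

    trait_code: str
    table: pd.DataFrame  # indexed by source

    def row(self, source: str) -> pd.Series:
        return self.table.loc[source]

    def p(self, source: str) -> float:
        return float(self.table.loc[source, "p"])

    def stars(self, source: str) -> str:
        return str(self.table.loc[source, "stars"])


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson correlations within one treatment."""

    treatment: str
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int
    legend: str = "* = p < 0.01, ** = p < 0.001"


@dataclass(frozen=True)
class LsdResult:
    """Fisher's protected LSD outcome for one factor of one trait."""

    trait_code: str
    factor: str
    alpha: float
    protected_skip: bool
    lsd_value: float | None
    means: pd.Series | None  # level -> mean, descending
    grouping: dict[str, str] | None  # level -> letters


def _pivot_balanced(obs: ObservationTable, trait: str, design: DesignSpec) -> np.ndarray:
    """(hybrid, treatment, replicate) value array; errors if unbalanced."""
    sub = obs.subset(trait=trait)
    if sub.empty:
        raise ValidationError(f"no observations for trait {trait!r}")
    reps = sorted(pd.unique(sub["replicate"]))
    r = design.n_replicates
    if len(reps) != r:
        raise ValidationError(
            f"trait {trait!r}: found replicate ids {reps}, expected {r} levels"
        )
    arr = np.full((len(design.hybrids), len(design.treatments), r), np.nan)
    hybrid_ix = {h: i for i, h in enumerate(design.hybrids)}
    treat_ix = {t: j for j, t in enumerate(design.treatments)}
    rep_ix = {k: m for m, k in enumerate(reps)}
    for row in sub.itertuples(index=False):
        arr[hybrid_ix[row.hybrid], treat_ix[row.treatment], rep_ix[row.replicate]] = row.value
    if np.isnan(arr).any():
        raise ValidationError(
            f"trait {trait!r}: unbalanced data — some hybrid x treatment x replicate "
            "cells are missing (only balanced designs are supported)"
        )
    return arr


def rcbd_anova(obs: ObservationTable, trait: str, design: DesignSpec) -> AnovaTable:
    """Two-factor RCBD ANOVA for one trait.

    The replicate id plays the block role: block SS is computed over the
    complete replicate sets. Sums of squares use the standard balanced-design
    partition; F ratios test each effect MS against the error MS, with
    upper-tail F p-values and star codes (strict 0.001/0.01/0.05 tiers).
    A zero error MS (e.g. noise-free synthetic data) yields F = inf, p = 0.
    """
    y = _pivot_balanced(obs, trait, design)  # (h, t, r)
    h, t, r = y.shape
    n = y.size
    if n - 1 - (r - 1) - (t - 1) - (h - 1) - (t - 1) * (h - 1) <= 0:
        raise ValidationError(
            f"zero error degrees of freedom for design h={h}, t={t}, r={r}"
        )
    grand = y.mean()
    cf = n * grand**2
    ss_total = float((y**2).sum() - cf)
    ss_block = float((y.sum(axis=(0, 1)) ** 2).sum() / (h * t) - cf)
    ss_treat = float((y.sum(axis=(0, 2)) ** 2).sum() / (h * r) - cf)
    ss_hybrid = float((y.sum(axis=(1, 2)) ** 2).sum() / (t * r) - cf)
    ss_cells = float((y.sum(axis=2) ** 2).sum() / r - cf)
    ss_int = ss_cells - ss_treat - ss_hybrid
    ss_error = ss_total - ss_block - ss_cells
    # guard tiny negative round-off
    ss_int = max(ss_int, 0.0)
    ss_error = max(ss_error, 0.0)

    df = {
        "block": r - 1,
        "treatment": t - 1,
        "hybrid": h - 1,
        "treatment:hybrid": (t - 1) * (h - 1),
    }
    df["error"] = (n - 1) - sum(df.values())
    df["total"] = n - 1
    ss = {
        "block": ss_block,
        "treatment": ss_treat,
        "hybrid": ss_hybrid,
        "treatment:hybrid": ss_int,
        "error": ss_error,
        "total": ss_total,
    }
    ms_error = ss_error / df["error"]
    rows = []
    for source in ANOVA_SOURCES:
        ms = ss[source] / df[source] if source != "total" and df[source] > 0 else np.nan
        if source in ("error", "total"):
            f_val, p_val, stars = np.nan, np.nan, ""
        else:
            if ms_error == 0:
                f_val = np.inf if ms > 0 else np.nan
                p_val = 0.0 if ms > 0 else np.nan
            else:
                f_val = ms / ms_error
                p_val = float(stats.f.sf(f_val, df[source], df["error"]))
            stars = star_code(p_val) if np.isfinite(p_val) else ""
        rows.append(dict(source=source, SS=ss[source], df=df[source], MS=ms,
                         F=f_val, p=p_val, stars=stars))
    table = pd.DataFrame(rows).set_index("source")
    return AnovaTable(trait_code=trait, table=table)


def _letter_display(means: pd.Series, lsd: float) -> dict[str, str]:
    """Compact letter display: levels sorted by descending mean; two levels
    share a letter iff their means differ by at most the LSD."""
    levels = list(means.index)
    m = means.to_numpy()
    segments: list[tuple[int, int]] = []
    for i in range(len(levels)):
        j = i
        while j + 1 < len(levels) and m[i] - m[j + 1] <= lsd + 1e-12:
            j += 1
        if segments and segments[-1][1] >= j:  # contained in the previous segment
            continue
        segments.append((i, j))
    letters = {lvl: "" for lvl in levels}
    for seg_ix, (i, j) in enumerate(segments):
        letter = chr(ord("a") + seg_ix)
        for k in range(i, j + 1):
            letters[levels[k]] += letter
    return letters


def fisher_lsd(
    anova: AnovaTable,
    obs: ObservationTable,
    trait: str,
    factor: str,
    design: DesignSpec,
    alpha: float = 0.05,
) -> LsdResult:
    """Fisher's protected LSD for ``factor`` ('treatment' or 'hybrid').

    Protected: if the omnibus F-test for the factor is not significant at
    ``alpha`` the comparison is skipped (``protected_skip=True``, no
    letters). Otherwise LSD = t(1 - alpha/2, df_error) * sqrt(2 MS_e / n),
    with n the per-level replication, and levels sharing a letter iff their
    mean difference is within the LSD.
    """
    if factor not in ("treatment", "hybrid"):
        raise ValidationError(f"factor must be 'treatment' or 'hybrid', got {factor!r}")
    p_factor = anova.p(factor)
    if not (p_factor < alpha):
        return LsdResult(trait, factor, alpha, True, None, None, None)
    ms_error = float(anova.row("error")["MS"])
    df_error = int(anova.row("error")["df"])
    levels = design.treatments if factor == "treatment" else design.hybrids
    n_per_level = design.n_units // len(levels)
    lsd = float(stats.t.ppf(1 - alpha / 2, df_error) * np.sqrt(2 * ms_error / n_per_level))
    sub = obs.subset(trait=trait)
    means = (
        sub.groupby(factor)["value"].mean().reindex(levels).sort_values(ascending=False)
    )
    return LsdResult(trait, factor, alpha, False, lsd, means, _letter_display(means, lsd))


def pearson_matrix(
    obs: ObservationTable,
    treatment: str,
    panel: Sequence[TraitDefinition] | None = None,
) -> CorrelationMatrix:
    """Pairwise Pearson correlations over replicate-level values within a treatment.

    Observations are paired by (hybrid, replicate); the published screen has
    n = 24 pairs (6 hybrids x 4 replicates) per treatment. Significance uses
    the exact t transform t = r sqrt(n-2)/sqrt(1-r^2) on n-2 df, two-sided.
    A zero-variance trait yields NaN (undefined), never 0.
    """
    sub = obs.subset(treatment=treatment)
    if sub.empty:
        raise ValidationError(f"no observations for treatment {treatment!r}")
    traits = [t.code for t in panel] if panel is not None else list(pd.unique(sub["trait"]))
    wide = sub.pivot(index=["hybrid", "replicate"], columns="trait", values="value")
    missing = [t for t in traits if t not in wide.columns]
    if missing:
        raise ValidationError(f"treatment {treatment!r} lacks traits {missing}")
    wide = wide[traits]
    if wide.isna().any().any():
        raise ValidationError(f"treatment {treatment!r}: incomplete trait x unit matrix")
    n = len(wide)
    if n < 3:
        raise ValidationError(f"need >= 3 paired observations, found {n}")
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    x = wide.to_numpy()
    sd = x.std(axis=0)
    for i in range(k):
        if sd[i] == 0:
            continue
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            if sd[j] == 0:
                continue
            res = stats.pearsonr(x[:, i], x[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=traits, columns=traits)
    p_df = pd.DataFrame(p, index=traits, columns=traits)
    stars = p_df.map(lambda v: corr_star_code(v) if np.isfinite(v) else "NA")
    return CorrelationMatrix(treatment=treatment, r=r_df, p=p_df, stars=stars, n=n)


def combined_matrix_report(
    corr_drought: CorrelationMatrix, corr_control: CorrelationMatrix
) -> pd.DataFrame:
    """Square string table: drought correlations above the diagonal, control
    below, ``1.000`` on the diagonal, star suffixes appended (NS omitted)."""
    traits = list(corr_drought.r.columns)
    if traits != list(corr_control.r.columns):
        raise ValidationError("correlation matrices cover different trait lists")

    def cell(src: CorrelationMatrix, a: str, b: str) -> str:
        r = src.r.loc[a, b]
        if not np.isfinite(r):
            return "NA"
        star = src.stars.loc[a, b]
        return f"{r:.3f}" + (star if star not in ("NS", "NA") else "")

    out = pd.DataFrame("", index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if i == j:
                out.loc[a, b] = "1.000"
            elif i < j:
                out.loc[a, b] = cell(corr_drought, a, b)
            else:
                out.loc[a, b] = cell(corr_control, a, b)
    return out
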
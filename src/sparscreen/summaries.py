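"""Treatment-level summary statistics and percent stress responses.

All quantities are computed from a :class:`~sparscreen.trait_model.TraitMeanTable`
on unrounded cell means; rounding to two decimals happens only at display
time. Percent changes follow the convention

    decline  = 100 * (control - drought) / control
    increase = 100 * (drought - control) / control

so a trait's decline and increase are exact negatives of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .trait_model import DesignSpec, TraitMeanTable, ValidationError

__all__ = [
    "PercentChange",
    "treatment_mean",
    "percent_change_overall",
    "percent_change_by_hybrid",
    "absolute_reduction",
    "extreme_responders",
    "summary_table",
]


@dataclass(frozen=True)
class PercentChange:
    """A percent stress response on the printed scale (e.g. 57.96 for 57.96%)."""

    trait_code: str
    scope: str  # "overall" or "hybrid:<name>"
    direction: str  # "decline" or "increase"
    value: float


def _check_direction(direction: str) -> None:
    if direction not in {"decline", "increase"}:
        raise ValidationError(f"direction must be 'decline' or 'increase', got {direction!r}")


def treatment_mean(means: TraitMeanTable, trait: str, treatment: str) -> float:
    """Unweighted arithmetic mean of one trait over all hybrids in one treatment."""
    vec = means.trait_vector(trait, treatment)
    if vec.isna().any():
        missing = list(vec.index[vec.isna()])
        raise ValidationError(f"trait {trait!r} missing for hybrids {missing} in treatment {treatment!r}")
    return float(vec.mean())


def _percent(c: float, d: float, direction: str, trait: str, scope: str) -> PercentChange:
    _check_direction(direction)
    if c == 0:
        raise ValidationError(f"control mean is 0 for trait {trait!r} ({scope}); percent change undefined")
    value = 100.0 * (c - d) / c
    if direction == "increase":
        value = -value
    return PercentChange(trait_code=trait, scope=scope, direction=direction, value=value)


def percent_change_overall(
    means: TraitMeanTable, trait: str, direction: str = "decline",
    design: DesignSpec | None = None,
) -> PercentChange:
    """Percent change of the across-hybrid treatment means for one trait."""
    drought, control = _labels(means, design)
    c = treatment_mean(means, trait, control)
    d = treatment_mean(means, trait, drought)
    return _percent(c, d, direction, trait, "overall")


def percent_change_by_hybrid(
    means: TraitMeanTable, trait: str, hybrid: str, direction: str = "decline",
    design: DesignSpec | None = None,
) -> PercentChange:
    """Percent change for one hybrid's cell means of one trait."""
    drought, control = _labels(means, design)
    c = means.mean(hybrid, control, trait)
    d = means.mean(hybrid, drought, trait)
    return _percent(c, d, direction, trait, f"hybrid:{hybrid}")


def absolute_reduction(
    means: TraitMeanTable, trait: str, hybrid: str, design: DesignSpec | None = None
) -> float:
    """Control minus drought cell mean, in the trait's own units."""
    drought, control = _labels(means, design)
    return means.mean(hybrid, control, trait) - means.mean(hybrid, drought, trait)


def extreme_responders(
    means: TraitMeanTable, trait: str, direction: str = "decline",
    design: DesignSpec | None = None,
) -> dict:
    """Hybrids with the largest and smallest percent change for a trait.

    Returns ``{"max": (hybrids, value), "min": (hybrids, value)}``; each
    ``hybrids`` entry is a list so exact ties are reported in full.
    """
    hybrids = means.hybrids
    if len(hybrids) < 2:
        raise ValidationError("extreme_responders requires at least two hybrids")
    changes = {
        h: percent_change_by_hybrid(means, trait, h, direction, design).value for h in hybrids
    }
    vmax = max(changes.values())
    vmin = min(changes.values())
    return {
        "max": (sorted(h for h, v in changes.items() if v == vmax), vmax),
        "min": (sorted(h for h, v in changes.items() if v == vmin), vmin),
    }


def _labels(means: TraitMeanTable, design: DesignSpec | None) -> tuple[str, str]:
    """(drought, control) treatment labels for a two-treatment mean table."""
    if design is not None:
        return design.drought_label, design.control_label
    treatments = means.treatments
    if len(treatments) != 2:
        raise ValidationError(
            f"cannot infer drought/control from treatments {treatments}; pass a DesignSpec"
        )
    # Fixture convention: D = drought, C = control; T1/T2 likewise.
    for drought, control in (("D", "C"), ("T1", "T2")):
        if set(treatments) == {drought, control}:
            return drought, control
    raise ValidationError(
        f"ambiguous treatment labels {treatments}; pass a DesignSpec with control_label"
    )


def summary_table(means: TraitMeanTable, design: DesignSpec | None = None) -> pd.DataFrame:
    """Per-trait and per-hybrid summary: control/drought means, percent decline, absolute reduction."""
    drought, control = _labels(means, design)
    rows = []
    for trait in means.traits:
        c = treatment_mean(means, trait, control)
        d = treatment_mean(means, trait, drought)
        rows.append(
            dict(trait=trait, scope="overall", mean_C=c, mean_D=d,
                 pct_decline=100.0 * (c - d) / c if c != 0 else float("nan"),
                 abs_reduction=c - d)
        )
        for h in means.hybrids:
            hc = means.mean(h, control, trait)
            hd = means.mean(h, drought, trait)
            rows.append(
                dict(trait=trait, scope=f"hybrid:{h}", mean_C=hc, mean_D=hd,
                     pct_decline=100.0 * (hc - hd) / hc if hc != 0 else float("nan"),
                     abs_reduction=hc - hd)
            )
    return pd.DataFrame(rows)
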
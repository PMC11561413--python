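"""Drought-stress response indices and tolerance classification.

The individual drought-stress response index (IDSRI) of a trait for one
hybrid is the ratio of the trait's cell mean under drought to its cell mean
under the irrigated control,

    IDSRI = P_drought / P_control,

and the cumulative index (CDSRI) is the plain sum of IDSRI over a fixed
panel of member traits (21 in the default panel). Ratios keep their natural
direction for every trait — traits that rise under drought (root-to-shoot
ratio, longest root length, root diameter) contribute ratios above 1 — so a
higher CDSRI reads as a more drought-tolerant hybrid. Hybrids are then split
into sensitive / moderate / tolerant classes by equal-width thirds of the
observed CDSRI range.

Note on the published six-hybrid trial: the CDSRI scores printed for it
(25.21-28.32) cannot be reproduced by applying the index formula to its
published trait means (which yield roughly 15-16); they were presumably
computed from unpublished replicate-level or differently scaled data.
:data:`PUBLISHED_CDSRI` carries the printed scores verbatim so the published
classification can be reproduced from them, and
:func:`cdsri_discrepancy_report` makes the mismatch explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .trait_model import (
    DesignSpec,
    TraitDefinition,
    TraitMeanTable,
    ValidationError,
)

__all__ = [
    "DsriResult",
    "ClassBounds",
    "PUBLISHED_CDSRI",
    "idsri",
    "idsri_profile",
    "cdsri",
    "score_all",
    "classify",
    "rank_hybrids",
    "cdsri_discrepancy_report",
]

CLASS_LABELS = ("sensitive", "moderate", "tolerant")

#: CDSRI scores printed for the published six-hybrid trial (classification
#: inputs only; see module docstring).
PUBLISHED_CDSRI: dict[str, float] = {
    "P-1319": 25.21,
    "N59B-311A": 25.34,
    "DKC-6697": 26.85,
    "P-1498": 26.89,
    "N61X-3110": 28.02,
    "DKC-6581": 28.32,
}


@dataclass(frozen=True)
class ClassBounds:
    """Three contiguous intervals partitioning the observed CDSRI range.

    Bins 1 and 2 are half-open ``[lo, hi)``; bin 3 is closed ``[lo, hi]``,
    so a score exactly on an interior edge lands in the upper bin.
    """

    edges: tuple[tuple[float, float], ...]
    method: str = "equal_width_observed"

    def assign(self, score: float) -> str:
        for label, (lo, hi) in zip(CLASS_LABELS[:-1], self.edges[:-1]):
            if lo <= score < hi:
                return label
        lo, hi = self.edges[-1]
        if lo <= score <= hi:
            return CLASS_LABELS[-1]
        raise ValidationError(f"score {score} outside classification range [{self.edges[0][0]}, {hi}]")


@dataclass(frozen=True)
class DsriResult:
    """Per-hybrid index profile: trait-wise IDSRI, their CDSRI sum, and class."""

    hybrid: str
    idsri: dict[str, float]
    cdsri: float
    class_label: str
    n_traits: int


def _drought_control(means: TraitMeanTable, design: DesignSpec | None) -> tuple[str, str]:
    from .summaries import _labels

    return _labels(means, design)


def idsri(
    means: TraitMeanTable, hybrid: str, trait: str, design: DesignSpec | None = None
) -> float:
    """Drought/control ratio of one trait's cell means for one hybrid."""
    drought, control = _drought_control(means, design)
    c = means.mean(hybrid, control, trait)
    if c == 0:
        raise ValidationError(
            f"control mean is 0 for trait {trait!r}, hybrid {hybrid!r}; IDSRI undefined"
        )
    return means.mean(hybrid, drought, trait) / c


def _member_traits(
    panel: Sequence[TraitDefinition], traits: Sequence[str] | None
) -> list[str]:
    members = [t.code for t in panel if t.cdsri_member]
    if traits is None:
        return members
    unknown = [t for t in traits if t not in {t_.code for t_ in panel}]
    if unknown:
        raise ValidationError(f"subset traits not in panel: {unknown}")
    return list(traits)


def idsri_profile(
    means: TraitMeanTable,
    hybrid: str,
    panel: Sequence[TraitDefinition],
    traits: Sequence[str] | None = None,
    design: DesignSpec | None = None,
) -> dict[str, float]:
    """IDSRI for every scored trait (member traits by default)."""
    member = _member_traits(panel, traits)
    profile, bad = {}, []
    for trait in member:
        try:
            profile[trait] = idsri(means, hybrid, trait, design)
        except ValidationError:
            bad.append(trait)
    if bad:
        raise ValidationError(
            f"IDSRI undefined or missing for hybrid {hybrid!r}, traits {bad}; "
            "pass an explicit trait subset to score without them"
        )
    return profile


def cdsri(
    means: TraitMeanTable,
    hybrid: str,
    panel: Sequence[TraitDefinition],
    traits: Sequence[str] | None = None,
    design: DesignSpec | None = None,
) -> float:
    """Sum of IDSRI over the panel's member traits (no renormalization).

    A missing member trait is a hard error: CDSRI magnitudes are only
    comparable at a fixed trait count. Score a reduced panel explicitly via
    ``traits``.
    """
    return float(sum(idsri_profile(means, hybrid, panel, traits, design).values()))


def score_all(
    means: TraitMeanTable,
    panel: Sequence[TraitDefinition],
    traits: Sequence[str] | None = None,
    design: DesignSpec | None = None,
) -> list[DsriResult]:
    """Score and classify every hybrid in a trait-mean table."""
    member = _member_traits(panel, traits)
    profiles = {
        h: idsri_profile(means, h, panel, member, design) for h in means.hybrids
    }
    scores = {h: float(sum(p.values())) for h, p in profiles.items()}
    classes, _ = classify(scores)
    return [
        DsriResult(hybrid=h, idsri=profiles[h], cdsri=scores[h],
                   class_label=classes[h], n_traits=len(member))
        for h in means.hybrids
    ]


def classify(
    scores: Mapping[str, float], method: str = "equal_width_observed"
) -> tuple[dict[str, str], ClassBounds]:
    """Split hybrids into sensitive/moderate/tolerant by CDSRI.

    The observed score range [min, max] is cut into three equal-width bins;
    increasing CDSRI maps to sensitive < moderate < tolerant. Requires at
    least three hybrids and a non-degenerate range.
    """
    if method != "equal_width_observed":
        raise ValidationError(f"unknown classification method {method!r}")
    if len(scores) < 3:
        raise ValidationError("classification requires at least 3 hybrids")
    lo, hi = min(scores.values()), max(scores.values())
    if lo == hi:
        raise ValidationError("all CDSRI scores equal; classification range is degenerate")
    width = (hi - lo) / 3.0
    bounds = ClassBounds(
        edges=((lo, lo + width), (lo + width, lo + 2 * width), (lo + 2 * width, hi))
    )
    return {h: bounds.assign(s) for h, s in scores.items()}, bounds


def rank_hybrids(scores: Mapping[str, float]) -> pd.DataFrame:
    """Hybrids by descending CDSRI; ties broken alphabetically and flagged."""
    frame = pd.DataFrame(
        {"hybrid": list(scores.keys()), "cdsri": list(scores.values())}
    ).sort_values(["cdsri", "hybrid"], ascending=[False, True], kind="stable")
    frame["rank"] = range(1, len(frame) + 1)
    frame["tied"] = frame["cdsri"].duplicated(keep=False)
    return frame.reset_index(drop=True)


def cdsri_discrepancy_report(
    means: TraitMeanTable,
    panel: Sequence[TraitDefinition],
    published: Mapping[str, float] = PUBLISHED_CDSRI,
    design: DesignSpec | None = None,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Recomputed vs published CDSRI per hybrid, flagging |difference| > tolerance."""
    rows = []
    for h in means.hybrids:
        recomputed = cdsri(means, h, panel, design=design)
        pub = published.get(h)
        diff = None if pub is None else recomputed - pub
        rows.append(
            dict(hybrid=h, recomputed=recomputed, published=pub, difference=diff,
                 discrepant=bool(diff is not None and abs(diff) > tolerance))
        )
    return pd.DataFrame(rows)
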
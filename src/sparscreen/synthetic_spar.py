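"""Synthetic SPAR-trial generator.

Produces replicate-level observation tables with the statistical structure
of the screening experiment — known hybrid x treatment cell means plus
independent within-cell noise — so every inference stage (ANOVA, LSD,
correlations, indices) is testable without external data. The default
configuration mirrors the published design: 6 hybrids x 2 treatments x 4
replicate columns x 22 traits, cell means taken from the packaged fixture,
and a within-cell coefficient of variation of 0.10 (the trial publishes no
replicate-level variance, so the noise level is a modeling default).

The noise model is independent normal per cell: no block effects and no
trait-trait covariance are simulated. Values for nonnegative traits are
truncated at zero by rejection (re-draw), keeping the distribution
continuous rather than piling mass at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trait_model import (
    DesignSpec,
    ObservationTable,
    TraitDefinition,
    TraitMeanTable,
    ValidationError,
    load_default_panel,
    load_table3_fixture,
)

__all__ = ["SyntheticConfig", "generate", "generate_layout"]

_MAX_REJECTIONS = 1000


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic trial.

    ``cv`` may be a single global coefficient of variation or a per-trait
    mapping; under ``normal_cv`` each value is drawn from
    Normal(mean, cv * |mean|). ``normal_sd`` instead uses ``sd`` as an
    absolute standard deviation for every cell.
    """

    mean_source: TraitMeanTable | None = None  # default: packaged fixture
    cv: float | dict[str, float] = 0.10
    sd: float = 1.0
    n_replicates: int = 4
    seed: int = 0
    noise_model: str = "normal_cv"
    truncate_nonnegative: bool = True
    panel: Sequence[TraitDefinition] | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.noise_model not in {"normal_cv", "normal_sd"}:
            raise ValidationError(f"unknown noise_model {self.noise_model!r}")
        cvs = self.cv.values() if isinstance(self.cv, dict) else [self.cv]
        if any(c < 0 for c in cvs):
            raise ValidationError("cv must be >= 0")
        if self.noise_model == "normal_sd" and self.sd < 0:
            raise ValidationError("sd must be >= 0")

    def trait_cv(self, trait: str) -> float:
        if isinstance(self.cv, dict):
            if trait not in self.cv:
                raise ValidationError(f"no cv configured for trait {trait!r}")
            return self.cv[trait]
        return self.cv


def _draw(rng: np.random.Generator, mean: float, sd: float, truncate: bool) -> float:
    if sd == 0:
        return mean
    for _ in range(_MAX_REJECTIONS):
        value = rng.normal(mean, sd)
        if not truncate or value >= 0:
            return float(value)
    raise ValidationError(
        f"rejection sampling failed for mean={mean}, sd={sd}: "
        "truncation at 0 rejects essentially every draw"
    )


def generate(config: SyntheticConfig) -> ObservationTable:
    """Generate one synthetic replicate-level observation table.

    Row order is deterministic — hybrids and treatments in mean-table order,
    replicates 1..n, traits in panel order — and a single RNG stream seeded
    from ``config.seed`` makes the output fully reproducible.
    """
    means = config.mean_source if config.mean_source is not None else load_table3_fixture()
    panel = list(config.panel) if config.panel is not None else load_default_panel()
    panel_codes = [t.code for t in panel if t.code in set(means.traits)]
    if not panel_codes:
        raise ValidationError("mean source contains no panel traits")
    nonneg = {t.code: t.nonnegative for t in panel}
    rng = np.random.default_rng(config.seed)
    rows = []
    for hybrid in means.hybrids:
        for treatment in means.treatments:
            for rep in range(1, config.n_replicates + 1):
                for trait in panel_codes:
                    mu = means.mean(hybrid, treatment, trait)
                    if config.noise_model == "normal_cv":
                        sd = config.trait_cv(trait) * abs(mu)
                    else:
                        sd = config.sd
                    truncate = config.truncate_nonnegative and nonneg[trait]
                    rows.append(
                        (hybrid, treatment, rep, trait, _draw(rng, mu, sd, truncate))
                    )
    frame = pd.DataFrame(
        rows, columns=["hybrid", "treatment", "replicate", "trait", "value"]
    )
    return ObservationTable(frame)


def generate_layout(design: DesignSpec, seed: int = 0) -> pd.DataFrame:
    """Randomized assignment of hybrids to numbered SPAR column positions.

    Positions are split into contiguous per-treatment blocks (drought and
    control columns are physically separate units); within each treatment the
    hybrid x replicate slots are randomly permuted. Every hybrid occupies
    exactly ``design.n_replicates`` positions per treatment.
    """
    rng = np.random.default_rng(seed)
    rows = []
    position = 1
    for treatment in design.treatments:
        slots = [h for h in design.hybrids for _ in range(design.n_replicates)]
        rng.shuffle(slots)
        for hybrid in slots:
            rows.append(dict(position=position, treatment=treatment, hybrid=hybrid))
            position += 1
    return pd.DataFrame(rows)
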
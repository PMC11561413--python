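"""Trait panel, experimental-design vocabulary, and phenotype-table containers.

The screening design is a two-factor randomized complete block experiment:
six maize hybrids grown under a drought treatment and an irrigated control
in soil-plant-atmosphere-research (SPAR) columns, four replicate columns per
hybrid x treatment cell, with 22 morpho-physiological traits scored at 28
days after sowing. This module defines:

* :class:`TraitDefinition` and the 22-trait default panel (21 of which enter
  the cumulative drought-stress response index, CDSRI);
* :class:`DesignSpec`, the hybrids/treatments/replication vocabulary;
* :class:`ObservationTable`, replicate-level long-format measurements;
* :class:`TraitMeanTable`, per-(hybrid, treatment, trait) cell means;
* the packaged trait-mean fixture for the published six-hybrid trial.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitDefinition",
    "DesignSpec",
    "ObservationTable",
    "TraitMeanTable",
    "TRAIT_ALIASES",
    "canonical_code",
    "load_default_panel",
    "load_table3_fixture",
    "fixture_design",
    "read_observations",
    "write_observations",
    "read_trait_means",
    "write_trait_means",
    "collapse_to_means",
    "PanelError",
    "ValidationError",
]

OBS_COLUMNS = ["hybrid", "treatment", "replicate", "trait", "value"]

#: Synonyms accepted on input and normalized to the panel's canonical codes.
#: RL (root length) and TRL (total root length) name the same scanned
#: quantity; ARD (average root diameter) maps to RD; RS to the
#: root-to-shoot ratio RSR.
TRAIT_ALIASES: dict[str, str] = {
    "RL": "TRL",
    "ARD": "RD",
    "RS": "RSR",
    "FVFM": "Fv/Fm",
    "FV/FM": "Fv/Fm",
    "PHOT": "Phot",
}


class PanelError(ValueError):
    """Raised when a trait panel is internally inconsistent."""


class ValidationError(ValueError):
    """Raised when input data fails structural validation."""


@dataclass(frozen=True)
class TraitDefinition:
    """One measured phenotype.

    Parameters
    ----------
    code
        Short identifier unique within a panel (e.g. ``PH``, ``SPAD``).
    label
        Human-readable name.
    units
        Free-text units (``cm plant-1``, ``unitless``, ...).
    category
        One of ``developmental``, ``root``, ``physiological``.
    cdsri_member
        Whether the trait's drought/control ratio enters the CDSRI sum.
    nonnegative
        Whether measured values must be >= 0.
    """

    code: str
    label: str
    units: str
    category: str
    cdsri_member: bool
    nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.category not in {"developmental", "root", "physiological"}:
            raise PanelError(f"unknown trait category {self.category!r} for {self.code}")


def _default_panel() -> list[TraitDefinition]:
    T = TraitDefinition
    return [
        T("PH", "plant height", "cm plant-1", "developmental", True),
        T("LN", "leaf number", "no. plant-1", "developmental", True),
        T("LA", "leaf area", "cm2 plant-1", "developmental", True),
        T("LDW", "leaf dry weight", "g plant-1", "developmental", True),
        T("SDW", "stem dry weight", "g plant-1", "developmental", True),
        T("SHDW", "shoot dry weight", "g plant-1", "root", True),
        T("RDW", "root dry weight", "g plant-1", "root", True),
        T("RSR", "root-to-shoot ratio", "unitless", "root", True),
        T("TDW", "total dry weight", "g plant-1", "developmental", True),
        T("RSA", "root surface area", "mm2 plant-1", "root", True),
        T("RD", "average root diameter", "mm plant-1", "root", True),
        T("TRL", "total root length", "cm plant-1", "root", True),
        T("RV", "root volume", "cm3 plant-1", "root", True),
        T("NRT", "number of root tips", "no. plant-1", "root", True),
        T("NRF", "number of root forks", "no. plant-1", "root", True),
        T("NRC", "number of root crossings", "no. plant-1", "root", True),
        T("LRL", "longest root length", "cm plant-1", "root", True),
        T("RN", "number of roots", "no. plant-1", "root", True),
        T("SPAD", "chlorophyll content (SPAD)", "unitless", "physiological", True),
        T("Phot", "net photosynthetic rate", "umol m-2 s-1", "physiological", True),
        T("Fv/Fm", "maximal PSII quantum yield", "unitless", "physiological", True),
        # ETR is scored but does not enter the cumulative index.
        T("ETR", "electron transport rate", "umol m-2 s-1", "physiological", False),
    ]


def load_default_panel() -> list[TraitDefinition]:
    """Return the default 22-trait panel (21 CDSRI members plus ETR)."""
    panel = _default_panel()
    codes = [t.code for t in panel]
    if len(set(codes)) != len(codes):
        raise PanelError("duplicate trait codes in panel")
    n_members = sum(t.cdsri_member for t in panel)
    if n_members != 21:
        raise PanelError(f"default panel must have 21 CDSRI members, found {n_members}")
    return panel


def canonical_code(code: str, panel: Sequence[TraitDefinition]) -> str:
    """Resolve ``code`` (or a recognized alias) to the panel's canonical code.

    Raises :class:`ValidationError` for unknown codes.
    """
    by_code = {t.code: t.code for t in panel}
    if code in by_code:
        return code
    alias = TRAIT_ALIASES.get(code) or TRAIT_ALIASES.get(code.upper())
    if alias is not None and alias in by_code:
        return alias
    raise ValidationError(f"unknown trait code {code!r}")


@dataclass(frozen=True)
class DesignSpec:
    """Hybrids, treatments and replication of a screening trial.

    ``control_label`` names the treatment used as the denominator of every
    drought/control ratio; the remaining treatment is taken as the stress
    treatment (:attr:`drought_label`).
    """

    hybrids: tuple[str, ...]
    treatments: tuple[str, ...] = ("T1", "T2")
    n_replicates: int = 4
    control_label: str = "T2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hybrids", tuple(self.hybrids))
        object.__setattr__(self, "treatments", tuple(self.treatments))
        if self.control_label not in self.treatments:
            raise ValidationError(
                f"control_label {self.control_label!r} not among treatments {self.treatments}"
            )
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if len(set(self.hybrids)) != len(self.hybrids):
            raise ValidationError("duplicate hybrid names")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValidationError("duplicate treatment labels")

    @property
    def drought_label(self) -> str:
        """The (single) non-control treatment."""
        others = [t for t in self.treatments if t != self.control_label]
        if len(others) != 1:
            raise ValidationError(
                "drought_label is only defined for two-treatment designs; "
                f"treatments are {self.treatments}"
            )
        return others[0]

    @property
    def n_units(self) -> int:
        return len(self.hybrids) * len(self.treatments) * self.n_replicates


class ObservationTable:
    """Replicate-level long-format measurements.

    Thin wrapper around a tidy :class:`pandas.DataFrame` with columns
    ``hybrid, treatment, replicate, trait, value`` and a unique
    (hybrid, treatment, replicate, trait) key.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in OBS_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"observation frame missing columns {missing}")
        frame = frame.loc[:, OBS_COLUMNS].reset_index(drop=True)
        dup = frame.duplicated(subset=["hybrid", "treatment", "replicate", "trait"])
        if dup.any():
            key = frame.loc[dup.idxmax(), ["hybrid", "treatment", "replicate", "trait"]]
            raise ValidationError(f"duplicate observation key {tuple(key)}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ObservationTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.frame["trait"]))

    @property
    def hybrids(self) -> list[str]:
        return list(pd.unique(self.frame["hybrid"]))

    @property
    def treatments(self) -> list[str]:
        return list(pd.unique(self.frame["treatment"]))

    def subset(self, *, treatment: str | None = None, trait: str | None = None) -> pd.DataFrame:
        f = self.frame
        if treatment is not None:
            f = f[f["treatment"] == treatment]
        if trait is not None:
            f = f[f["trait"] == trait]
        return f

    def validate(self, panel: Sequence[TraitDefinition], design: DesignSpec) -> "ObservationTable":
        """Check labels and sign constraints against a panel and design."""
        by_code = {t.code: t for t in panel}
        for idx, row in self.frame.iterrows():
            if row["trait"] not in by_code:
                raise ValidationError(f"row {idx}: unknown trait {row['trait']!r}")
            if row["hybrid"] not in design.hybrids:
                raise ValidationError(f"row {idx}: unknown hybrid {row['hybrid']!r}")
            if row["treatment"] not in design.treatments:
                raise ValidationError(f"row {idx}: unknown treatment {row['treatment']!r}")
            if by_code[row["trait"]].nonnegative and row["value"] < 0:
                raise ValidationError(
                    f"row {idx}: negative value {row['value']} for nonnegative trait {row['trait']}"
                )
        return self


class TraitMeanTable:
    """Per-(hybrid, treatment, trait) cell means, optionally with SE and n.

    The table must be complete over hybrids x treatments for every trait it
    contains; a missing cell is a load-time error, never silently absent.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["trait", "hybrid", "treatment", "mean"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValidationError(f"trait-mean frame missing columns {missing}")
        cols = required + [c for c in ("se", "n") if c in frame.columns]
        frame = frame.loc[:, cols].reset_index(drop=True)
        dup = frame.duplicated(subset=["trait", "hybrid", "treatment"])
        if dup.any():
            key = frame.loc[dup.idxmax(), ["trait", "hybrid", "treatment"]]
            raise ValidationError(f"duplicate trait-mean cell {tuple(key)}")
        self.frame = frame
        self._check_complete()
        self._lookup = frame.set_index(["trait", "hybrid", "treatment"])["mean"]

    def _check_complete(self) -> None:
        hybrids = list(pd.unique(self.frame["hybrid"]))
        treatments = list(pd.unique(self.frame["treatment"]))
        counts = self.frame.groupby("trait", sort=False).size()
        expected = len(hybrids) * len(treatments)
        bad = counts[counts != expected]
        if len(bad):
            raise ValidationError(
                f"incomplete trait-mean table: traits {list(bad.index)} do not cover "
                f"all {len(hybrids)} hybrids x {len(treatments)} treatments"
            )

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.frame["trait"]))

    @property
    def hybrids(self) -> list[str]:
        return list(pd.unique(self.frame["hybrid"]))

    @property
    def treatments(self) -> list[str]:
        return list(pd.unique(self.frame["treatment"]))

    def mean(self, hybrid: str, treatment: str, trait: str) -> float:
        """The cell mean for (hybrid, treatment, trait)."""
        try:
            return float(self._lookup.loc[(trait, hybrid, treatment)])
        except KeyError:
            raise ValidationError(
                f"no cell ({hybrid!r}, {treatment!r}, {trait!r}) in trait-mean table"
            ) from None

    def trait_vector(self, trait: str, treatment: str) -> pd.Series:
        """Per-hybrid means of one trait under one treatment (hybrid order preserved)."""
        f = self.frame
        sub = f[(f["trait"] == trait) & (f["treatment"] == treatment)]
        if sub.empty:
            raise ValidationError(f"no entries for trait {trait!r}, treatment {treatment!r}")
        return sub.set_index("hybrid")["mean"].reindex(self.hybrids)


# SHA-256 of the canonicalized packaged fixture (trait,hybrid,treatment,4-dp value).
_FIXTURE_SHA256 = "e9f5eed9049286055684703b901ca07d092869ac177c456fc364fc71c6febe3a"


def _fixture_checksum(frame: pd.DataFrame) -> str:
    parts = [
        f"{r.trait},{r.hybrid},{r.treatment},{r.mean:.4f}"
        for r in frame.itertuples()
    ]
    return hashlib.sha256("\n".join(parts).encode()).hexdigest()


def load_table3_fixture(verify: bool = True) -> TraitMeanTable:
    """The packaged six-hybrid trait-mean table (22 traits x 6 hybrids x 2 treatments).

    Treatments are labelled ``D`` (drought) and ``C`` (irrigated control).
    With ``verify`` (default) an SHA-256 over the canonicalized values guards
    against fixture corruption.
    """
    with resources.files("sparscreen.data").joinpath("table3_means.csv").open("r") as fh:
        frame = pd.read_csv(fh)
    if verify and _fixture_checksum(frame) != _FIXTURE_SHA256:
        raise ValidationError("packaged trait-mean fixture failed its integrity checksum")
    return TraitMeanTable(frame)


def fixture_design() -> DesignSpec:
    """Design matching the packaged fixture: 6 hybrids, D vs C, 4 replicates."""
    return DesignSpec(
        hybrids=("P-1498", "P-1319", "DKC-6581", "DKC-6697", "N61X-3110", "N59B-311A"),
        treatments=("D", "C"),
        n_replicates=4,
        control_label="C",
    )


def read_observations(
    path: str | Path,
    panel: Sequence[TraitDefinition],
    design: DesignSpec,
) -> ObservationTable:
    """Read and validate a long-format observations CSV.

    The file must carry the header ``hybrid,treatment,replicate,trait,value``
    (comma-separated, UTF-8, ``.`` decimal). Unknown labels, duplicate keys,
    non-numeric values and sign violations are rejected with the offending
    row number (1-based, excluding the header).
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in OBS_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    raw = raw.loc[:, OBS_COLUMNS]
    values = pd.to_numeric(raw["value"], errors="coerce")
    bad = values.isna()
    if bad.any():
        rownum = int(bad.idxmax()) + 1
        raise ValidationError(f"{path}: non-numeric value {raw['value'][bad.idxmax()]!r} at data row {rownum}")
    by_code = {t.code: t for t in panel}
    frame = raw.assign(value=values)
    # replicate ids are usually integers; keep labels as-is otherwise
    reps = pd.to_numeric(frame["replicate"], errors="coerce")
    if not reps.isna().any():
        if (reps == reps.astype(int)).all():
            reps = reps.astype(int)
        frame["replicate"] = reps
    frame["trait"] = [
        _resolve_or_fail(code, panel, path, i) for i, code in enumerate(frame["trait"], start=1)
    ]
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        if row.hybrid not in design.hybrids:
            raise ValidationError(f"{path}: unknown hybrid {row.hybrid!r} at data row {i}")
        if row.treatment not in design.treatments:
            raise ValidationError(f"{path}: unknown treatment {row.treatment!r} at data row {i}")
        if by_code[row.trait].nonnegative and row.value < 0:
            raise ValidationError(
                f"{path}: negative value {row.value} for nonnegative trait {row.trait} at data row {i}"
            )
    try:
        return ObservationTable(frame)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def _resolve_or_fail(code: str, panel: Sequence[TraitDefinition], path, rownum: int) -> str:
    try:
        return canonical_code(code, panel)
    except ValidationError:
        raise ValidationError(f"{path}: unknown trait {code!r} at data row {rownum}") from None


def write_observations(obs: ObservationTable, path: str | Path) -> None:
    """Write a long-format observations CSV (full float precision, round-trip safe)."""
    obs.frame.to_csv(path, index=False)


def write_trait_means(means: TraitMeanTable, path: str | Path) -> None:
    means.frame.to_csv(path, index=False)


def read_trait_means(path: str | Path) -> TraitMeanTable:
    """Read a long-format trait-mean CSV (columns trait,hybrid,treatment,mean[,se,n])."""
    return TraitMeanTable(pd.read_csv(path))


def collapse_to_means(obs: ObservationTable) -> TraitMeanTable:
    """Collapse replicate-level observations to per-cell mean, SE and n.

    SE is the standard error of the mean, sd/sqrt(n) with the sample (n-1)
    standard deviation; cells with a single replicate get SE = NaN.
    """
    if len(obs) == 0:
        raise ValidationError("cannot collapse an empty observation table")
    g = obs.frame.groupby(["trait", "hybrid", "treatment"], sort=False)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se"] = np.nan
    return TraitMeanTable(out.drop(columns="sd"))
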
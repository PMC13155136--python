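"""Domain types and delimited-file I/O for limiting dilution assay counts.

An LDA experiment scores, for each expected number of cells seeded per well
``S``, how many of ``n`` replicate wells fail to show clonogenic growth
(``Y`` negative wells).  The types here hold those counts per treatment and
biological replicate, validate the obvious invariants (``0 <= Y <= n``,
``S > 0``), read and write the CSV layout, and pool replicates by summing
well counts at matched dilutions.

The canonical stored response is the number of *negative* wells, because the
likelihood of the growth model is written on failures; input files may report
positive wells instead and are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError, PoolingError, SchemaError, ValidationError

__all__ = [
    "DilutionObservation",
    "AssayGroup",
    "LDAExperiment",
    "read_lda_table",
    "write_lda_table",
    "pool_replicates",
    "POOLED",
    "DEFAULT_SCHEMA",
]

#: Replicate label given to groups produced by :func:`pool_replicates`.
POOLED = "pooled"

#: Dilutions are matched across replicates after rounding S to this many
#: decimals; dilution series are specified values, not measurements.
S_MATCH_DECIMALS = 6

DEFAULT_SCHEMA: Mapping[str, str] = {
    "treatment": "treatment",
    "replicate": "replicate",
    "cells_per_well": "cells_per_well",
    "n_wells": "n_wells",
    "n_positive": "n_positive",
    "n_negative": "n_negative",
}


@dataclass(frozen=True)
class DilutionObservation:
    """One dilution step: ``S`` cells per well, ``n`` wells, ``Y`` negative.

    Parameters
    ----------
    cells_per_well : float
        Expected number of cells seeded per well (S).  Positive, possibly
        fractional: geometric series routinely start below one cell per well.
    n_wells : int
        Number of technical replicate wells at this dilution (n).
    n_negative : int
        Number of wells without clonogenic growth (Y), ``0 <= Y <= n``.
    """

    cells_per_well: float
    n_wells: int
    n_negative: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.cells_per_well) or self.cells_per_well <= 0:
            raise ValidationError(
                f"cells_per_well must be a positive finite number, got "
                f"{self.cells_per_well!r}"
            )
        if int(self.n_wells) != self.n_wells or self.n_wells < 1:
            raise ValidationError(f"n_wells must be a positive integer, got {self.n_wells!r}")
        if int(self.n_negative) != self.n_negative or self.n_negative < 0:
            raise ValidationError(
                f"n_negative must be a non-negative integer, got {self.n_negative!r}"
            )
        if self.n_negative > self.n_wells:
            raise ValidationError(
                f"n_negative ({self.n_negative}) exceeds n_wells ({self.n_wells}) "
                f"at cells_per_well={self.cells_per_well}"
            )

    @property
    def failure_fraction(self) -> float:
        """Observed fraction of wells without growth, Y / n."""
        return self.n_negative / self.n_wells


@dataclass(frozen=True)
class AssayGroup:
    """All dilution observations for one (treatment, replicate) pair."""

    treatment: str
    replicate: str
    observations: tuple[DilutionObservation, ...]

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        if len(obs) == 0:
            raise ValidationError(
                f"group ({self.treatment!r}, {self.replicate!r}) has no observations"
            )

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def cells_per_well(self) -> np.ndarray:
        return np.array([o.cells_per_well for o in self.observations], dtype=float)

    @property
    def n_wells(self) -> np.ndarray:
        return np.array([o.n_wells for o in self.observations], dtype=int)

    @property
    def n_negative(self) -> np.ndarray:
        return np.array([o.n_negative for o in self.observations], dtype=int)

    @property
    def all_negative(self) -> bool:
        """True when not a single well in the group shows clonogenic growth."""
        return bool(np.all(self.n_negative == self.n_wells))

    @property
    def all_positive(self) -> bool:
        """True when every well in the group shows clonogenic growth."""
        return bool(np.all(self.n_negative == 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatment,
                "replicate": self.replicate,
                "cells_per_well": self.cells_per_well,
                "n_wells": self.n_wells,
                "n_negative": self.n_negative,
            }
        )


@dataclass
class LDAExperiment:
    """A collection of assay groups plus the designated untreated reference."""

    groups: list[AssayGroup]
    reference_treatment: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for g in self.groups:
            key = (g.treatment, g.replicate)
            if key in seen:
                raise ValidationError(f"duplicate (treatment, replicate) pair {key!r}")
            seen.add(key)
        if self.reference_treatment not in self.treatments:
            raise ValidationError(
                f"reference treatment {self.reference_treatment!r} not found among "
                f"treatments {self.treatments}"
            )

    @property
    def treatments(self) -> list[str]:
        """Treatment labels in first-appearance order."""
        out: list[str] = []
        for g in self.groups:
            if g.treatment not in out:
                out.append(g.treatment)
        return out

    @property
    def replicates(self) -> list[str]:
        out: list[str] = []
        for g in self.groups:
            if g.replicate not in out:
                out.append(g.replicate)
        return out

    def groups_for(self, treatment: str) -> list[AssayGroup]:
        out = [g for g in self.groups if g.treatment == treatment]
        if not out:
            raise InputError(f"no groups for treatment {treatment!r}")
        return out

    def pooled_group(self, treatment: str) -> AssayGroup:
        """Well counts for ``treatment`` summed over biological replicates."""
        return pool_replicates(self.groups_for(treatment))

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([g.to_frame() for g in self.groups], ignore_index=True)


def _resolve_schema(columns: Sequence[str], schema: Mapping[str, str] | None):
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    resolved: dict[str, str] = {}
    for canonical in ("treatment", "replicate", "cells_per_well", "n_wells"):
        name = mapping[canonical]
        if name not in columns:
            raise SchemaError(
                f"required column {name!r} (for {canonical!r}) not found; "
                f"available columns: {list(columns)}"
            )
        resolved[canonical] = name
    has_neg = mapping["n_negative"] in columns
    has_pos = mapping["n_positive"] in columns
    if not (has_neg or has_pos):
        raise SchemaError(
            f"neither {mapping['n_negative']!r} nor {mapping['n_positive']!r} found; "
            f"one response column is required"
        )
    resolved["response"] = mapping["n_negative"] if has_neg else mapping["n_positive"]
    resolved["response_is_negative"] = has_neg  # type: ignore[assignment]
    return resolved


def read_lda_table(
    path,
    schema: Mapping[str, str] | None = None,
    reference_treatment: str | None = None,
) -> LDAExperiment:
    """Read a CSV count table into a validated :class:`LDAExperiment`.

    The file must have a header row with (default names) ``treatment``,
    ``replicate``, ``cells_per_well``, ``n_wells`` and either ``n_negative``
    or ``n_positive``; ``schema`` maps canonical names onto the file's own
    column names.  If positive wells are reported the stored response is
    ``n_negative = n_wells - n_positive``.  Row order is preserved within
    groups.

    ``reference_treatment`` defaults to the first treatment in the file.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty input file: {path}") from exc
    if df.empty:
        raise InputError(f"input file has a header but no data rows: {path}")
    cols = _resolve_schema(list(df.columns), schema)
    return experiment_from_frame(
        df.rename(
            columns={
                cols["treatment"]: "treatment",
                cols["replicate"]: "replicate",
                cols["cells_per_well"]: "cells_per_well",
                cols["n_wells"]: "n_wells",
                cols["response"]: "n_negative" if cols["response_is_negative"] else "n_positive",
            }
        ),
        reference_treatment=reference_treatment,
    )


def experiment_from_frame(
    df: pd.DataFrame, reference_treatment: str | None = None
) -> LDAExperiment:
    """Build an experiment from a canonical-column DataFrame (see
    :func:`read_lda_table` for the layout)."""
    df = df.copy()
    if "n_negative" not in df.columns:
        if "n_positive" not in df.columns:
            raise SchemaError("need an 'n_negative' or 'n_positive' column")
        df["n_negative"] = df["n_wells"] - df["n_positive"]

    groups: list[AssayGroup] = []
    # groupby(sort=False) keeps first-appearance order of (treatment, replicate)
    for (treatment, replicate), sub in df.groupby(["treatment", "replicate"], sort=False):
        obs = []
        for idx, row in sub.iterrows():
            try:
                obs.append(
                    DilutionObservation(
                        cells_per_well=float(row["cells_per_well"]),
                        n_wells=int(row["n_wells"]),
                        n_negative=int(row["n_negative"]),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {idx}: {exc}") from exc
        groups.append(AssayGroup(str(treatment), str(replicate), tuple(obs)))

    if reference_treatment is None:
        reference_treatment = groups[0].treatment
    return LDAExperiment(groups=groups, reference_treatment=reference_treatment)


def write_lda_table(experiment: LDAExperiment, path) -> None:
    """Write the experiment back out in the canonical CSV layout."""
    experiment.to_frame().to_csv(path, index=False)


def pool_replicates(groups: Iterable[AssayGroup]) -> AssayGroup:
    """Sum well counts across biological replicates of one treatment.

    All groups must carry the same treatment label and the same dilution
    series (S matched exactly after rounding to ``S_MATCH_DECIMALS``
    decimals).  Per distinct S, ``n_wells`` and ``n_negative`` are added; the
    replicate label of the result is the :data:`POOLED` sentinel.
    """
    groups = list(groups)
    if not groups:
        raise InputError("no groups to pool")
    treatments = {g.treatment for g in groups}
    if len(treatments) > 1:
        raise InputError(f"cannot pool across treatments: {sorted(treatments)}")
    if len(groups) == 1:
        g = groups[0]
        return AssayGroup(g.treatment, POOLED, g.observations)

    def keyed(g: AssayGroup) -> dict[float, DilutionObservation]:
        out: dict[float, DilutionObservation] = {}
        for o in g.observations:
            key = round(o.cells_per_well, S_MATCH_DECIMALS)
            if key in out:  # same S twice within a replicate: merge counts
                prev = out[key]
                o = DilutionObservation(
                    prev.cells_per_well,
                    prev.n_wells + o.n_wells,
                    prev.n_negative + o.n_negative,
                )
            out[key] = o
        return out

    maps = [keyed(g) for g in groups]
    reference_keys = list(maps[0])
    key_sets = [set(m) for m in maps]
    union = set().union(*key_sets)
    common = set.intersection(*key_sets)
    if union != common:
        unmatched = sorted(union - common)
        raise PoolingError(
            f"dilution series differ across replicates of treatment "
            f"{groups[0].treatment!r}; unmatched cells_per_well values: {unmatched}"
        )

    pooled_obs = []
    for key in reference_keys:
        n = sum(m[key].n_wells for m in maps)
        y = sum(m[key].n_negative for m in maps)
        pooled_obs.append(DilutionObservation(maps[0][key].cells_per_well, n, y))
    return AssayGroup(groups[0].treatment, POOLED, tuple(pooled_obs))
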
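"""Derived ecological covariates for areal analyses.

Expected counts and standardized morbidity ratios (internal
standardization against the pooled regional rate), three ethnic
diversity measures (normalized entropy, Simpson, and a neighbourhood
diversity index relative to a metropolitan reference composition), and
the Index of Concentration at the Extremes (ICE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OutcomeTable:
    """Per-area observed counts, survey sizes, expected counts and SMRs."""

    area_id: list[str]
    observed: np.ndarray
    surveyed: np.ndarray
    expected: np.ndarray
    smr: np.ndarray
    cutoff: str = "EDS>12"

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.surveyed = np.asarray(self.surveyed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        self.smr = np.asarray(self.smr, dtype=float)
        n = len(self.area_id)
        for name in ("observed", "surveyed", "expected", "smr"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of areas")
        if (self.observed > self.surveyed).any():
            raise ValueError("observed exceeds surveyed in some area")
        if (self.observed < 0).any():
            raise ValueError("negative observed counts")

    @property
    def n(self) -> int:
        return len(self.area_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_id": self.area_id,
                "observed": self.observed.astype(int),
                "surveyed": self.surveyed.astype(int),
                "expected": self.expected,
                "smr": self.smr,
            }
        )

    @classmethod
    def from_counts(
        cls, area_id, observed, surveyed, cutoff: str = "EDS>12"
    ) -> "OutcomeTable":
        """Build a table with internally standardized expected counts."""
        expected, smr = expected_counts(observed, surveyed)
        return cls(
            area_id=list(area_id),
            observed=np.asarray(observed, dtype=float),
            surveyed=np.asarray(surveyed, dtype=float),
            expected=expected,
            smr=smr,
            cutoff=cutoff,
        )


@dataclass
class EthnicComposition:
    """Per-area ethnic proportions plus the metropolitan reference vector."""

    area_id: list[str]
    proportions: np.ndarray  # (n_areas, R)
    metro_reference: np.ndarray  # (R,)
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.metro_reference = np.asarray(self.metro_reference, dtype=float)
        if self.proportions.ndim != 2:
            raise ValueError("proportions must be a 2-d (areas x categories) array")
        if self.proportions.shape[1] != len(self.metro_reference):
            raise ValueError("metro reference has different category count")
        if (self.proportions < 0).any() or (self.metro_reference < 0).any():
            raise ValueError("negative proportions")
        rows = self.proportions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            bad = np.flatnonzero(~np.isclose(rows, 1.0, atol=1e-9))
            raise ValueError(f"rows do not sum to 1: areas {bad.tolist()}")


def expected_counts(observed, surveyed, denominator=None):
    """Internally standardized expected counts and SMRs.

    The regional rate is total observed over total denominator;
    ``expected_i = rate * denominator_i``, so total expected equals total
    observed by construction.  ``denominator`` defaults to ``surveyed``;
    passing an alternative vector (e.g. women of child-bearing age)
    switches the standardization basis with no other change.

    Returns ``(expected, smr)``.  SMR is observed/expected, defined as 0
    (with a warning) where expected is 0.
    """
    observed = np.asarray(observed, dtype=float)
    denom = np.asarray(surveyed if denominator is None else denominator, dtype=float)
    if observed.shape != denom.shape:
        raise ValueError("observed and denominator lengths differ")
    if (denom <= 0).any():
        bad = np.flatnonzero(denom <= 0).tolist()
        raise ValueError(f"non-positive denominator in areas {bad}; drop them upstream")
    if (observed < 0).any():
        raise ValueError("negative observed counts")
    total = denom.sum()
    rate = observed.sum() / total
    expected = rate * denom
    with np.errstate(divide="ignore", invalid="ignore"):
        smr = np.where(expected > 0, observed / np.where(expected > 0, expected, 1.0), 0.0)
    if (expected == 0).any():
        warnings.warn("all-zero observed counts: SMR set to 0 everywhere", stacklevel=2)
    return expected, smr


def _check_proportions(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("need a 1-d proportion vector over >= 2 categories")
    if (p < 0).any():
        raise ValueError("negative proportions")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"proportions sum to {p.sum()}, expected 1")
    return p


def entropy_index(p, normalized: bool = True) -> float:
    """Entropy diversity of a composition, in [0, 1] when normalized.

    ``E = -sum(p_r ln p_r) / ln R`` with ``0 ln 0 := 0``.  0 means one
    category holds everything; 1 means a uniform spread.  With
    ``normalized=False`` the raw entropy (nats) is returned.
    """
    p = _check_proportions(p)
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / np.log(len(p)) if normalized else h


def simpson_index(p) -> float:
    """Simpson diversity ``1 - sum(p_r^2)``.

    0 for a single-category composition; approaches (but never reaches) 1
    as many categories share evenly — the maximum is ``1 - 1/R``.
    """
    p = _check_proportions(p)
    return float(1.0 - (p**2).sum())


def maly_index(p_area, p_metro) -> float:
    """Neighbourhood diversity relative to the metropolitan composition.

    ``ND = 1 - sum_r |p_area_r - p_metro_r| / 2``: one minus half the L1
    divergence, so an area matching the metropolitan mix scores 1 and an
    area wholly concentrated in a category the metro lacks scores near 0.
    """
    p_area = _check_proportions(p_area)
    p_metro = _check_proportions(p_metro)
    if len(p_area) != len(p_metro):
        raise ValueError("area and metro compositions have different category counts")
    return float(1.0 - np.abs(p_area - p_metro).sum() / 2.0)


def ice(affluent, poor, total) -> float:
    """Index of Concentration at the Extremes: (affluent - poor) / total.

    Ranges from -1 (all families poor) through 0 (balanced) to +1 (all
    affluent).
    """
    affluent, poor, total = float(affluent), float(poor), float(total)
    if total <= 0:
        raise ValueError("total must be positive")
    if affluent < 0 or poor < 0:
        raise ValueError("counts must be non-negative")
    if affluent + poor > total + 1e-12:
        raise ValueError("affluent + poor exceeds total")
    return (affluent - poor) / total


def diversity_table(comp: EthnicComposition) -> pd.DataFrame:
    """Entropy, Simpson and neighbourhood-diversity indices for each area."""
    rows = []
    for i, aid in enumerate(comp.area_id):
        p = comp.proportions[i]
        rows.append(
            {
                "area_id": aid,
                "entropy": entropy_index(p),
                "simpson": simpson_index(p),
                "maly": maly_index(p, comp.metro_reference),
            }
        )
    return pd.DataFrame(rows)
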
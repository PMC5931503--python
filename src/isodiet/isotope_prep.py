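"""Preparation of isotope data: delta conversion, sibling averaging, source aggregation."""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from collections.abc import Iterable, Sequence

import numpy as np

from isodiet.types import ConsumerObservation, IsotopeSample, SourceSpec, ValidationError

logger = logging.getLogger(__name__)


def delta_value(r_sample: float, r_standard: float) -> float:
    """Convert an isotope abundance ratio to a permil delta value.

    delta = (r_sample / r_standard - 1) * 1000, relative to the
    international standard ratio (PDB for carbon, atmospheric N2 for
    nitrogen).

    Raises
    ------
    ValidationError
        If ``r_standard`` is not strictly positive or ``r_sample`` is
        negative.
    """
    if not (r_standard > 0):
        raise ValidationError(f"standard ratio must be > 0, got {r_standard}")
    if r_sample < 0:
        raise ValidationError(f"sample ratio must be >= 0, got {r_sample}")
    return (r_sample / r_standard - 1.0) * 1000.0


def average_siblings(samples: Iterable[IsotopeSample]) -> list[ConsumerObservation]:
    """Collapse sibling feather samples into one observation per (territory, year).

    Means are unweighted arithmetic means.  A sample missing one isotope
    (``None``/NaN) contributes only to the other isotope's mean; this is
    logged as a warning.  Output is sorted by (territory, year).
    """
    groups: dict[tuple[str, int], list[IsotopeSample]] = defaultdict(list)
    for s in samples:
        if s.year is None:
            raise ValidationError(f"sample for territory {s.territory_id!r} has no year")
        groups[(str(s.territory_id), int(s.year))].append(s)

    out: list[ConsumerObservation] = []
    for (territory, year), members in sorted(groups.items()):
        c_vals = [s.delta13C for s in members if s.delta13C is not None and not math.isnan(s.delta13C)]
        n_vals = [s.delta15N for s in members if s.delta15N is not None and not math.isnan(s.delta15N)]
        if len(c_vals) < len(members) or len(n_vals) < len(members):
            logger.warning(
                "territory %s year %s: missing isotope values averaged pairwise",
                territory,
                year,
            )
        if not c_vals or not n_vals:
            raise ValidationError(
                f"territory {territory} year {year}: no usable values for one isotope"
            )
        out.append(
            ConsumerObservation(
                territory_id=territory,
                year=year,
                mean_delta13C=float(np.mean(c_vals)),
                mean_delta15N=float(np.mean(n_vals)),
                n_siblings=len(members),
            )
        )
    return out


def _mixture_moments(mus: np.ndarray, sds: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    # Equal-weight finite mixture: law of total variance.
    mean = float(weights @ mus)
    var = float(weights @ (sds**2 + mus**2) - mean**2)
    return mean, math.sqrt(max(var, 0.0))


def _stratified_mean_moments(
    mus: np.ndarray, sds: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    # Variance of the stratified (weighted-mean) estimator.
    mean = float(weights @ mus)
    var = float(weights**2 @ sds**2)
    return mean, math.sqrt(max(var, 0.0))


def aggregate_sources(
    components: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
    method: str = "mixture",
) -> tuple[float, float]:
    """Aggregate per-prey (mu, sd) pairs for one isotope into a category (mu, sd).

    Prey types receive equal weight by default (stratified sampling with
    equal strata).  ``method='mixture'`` (default) returns the spread of a
    randomly drawn prey item — the quantity the mixing model needs —
    via the law of total variance; ``method='stratified_mean'`` returns
    the smaller spread of the stratified mean itself.
    """
    if not components:
        raise ValidationError("at least one component required")
    mus = np.array([c[0] for c in components], dtype=float)
    sds = np.array([c[1] for c in components], dtype=float)
    if np.any(sds < 0):
        raise ValidationError("component SDs must be >= 0")
    if weights is None:
        w = np.full(len(components), 1.0 / len(components))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(components) or np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be non-negative and match components")
        w = w / w.sum()
    if method == "mixture":
        return _mixture_moments(mus, sds, w)
    if method == "stratified_mean":
        return _stratified_mean_moments(mus, sds, w)
    raise ValidationError(f"unknown aggregation method {method!r}")


def build_source_spec(
    name: str,
    components: Sequence[tuple[str, float, float, float, float]],
    method: str = "mixture",
) -> SourceSpec:
    """Build a category :class:`SourceSpec` from per-prey component rows."""
    mu13, sd13 = aggregate_sources([(c[1], c[2]) for c in components], method=method)
    mu15, sd15 = aggregate_sources([(c[3], c[4]) for c in components], method=method)
    return SourceSpec(
        name=name,
        mu13C=mu13,
        sd13C=sd13,
        mu15N=mu15,
        sd15N=sd15,
        components=tuple(tuple(c) for c in components),
    )
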
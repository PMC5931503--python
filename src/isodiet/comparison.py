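"""Method-agreement statistics between mixing-model and remains-based diets.

Three complementary analyses per food category, plus mean differences:

* weighted kappa on within-nest consumption ranks (ordinal agreement);
* intraclass correlation on the proportion estimates (absolute agreement);
* a posterior resampling test: for each nest-year, draw values from the
  mixing-model posterior and report the probability that the draw
  exceeds the conventional proportion (the fraction of conventional-
  minus-draw differences below zero) — a symmetric distribution of
  these fractions with median near 0.5 means the methods agree for that
  category; medians near 0 mean the conventional estimate is the larger
  one, near 1 the smaller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from isodiet.mixing_model import DietPosterior, FitSummary
from isodiet.types import CATEGORIES, DietProportions, ValidationError

logger = logging.getLogger(__name__)

RANK_GRID = tuple(np.arange(1.0, 5.5, 0.5))  # shared ordinal levels for 5-category ranks


@dataclass(frozen=True)
class PairedDietTable:
    """Nest-years present in both methods, with aligned 5-category proportions.

    ``conventional`` and ``sia_mean`` are (n_nest_years, 5) arrays in the
    canonical category order; ``posterior_index`` maps each row to its
    consumer in ``posterior`` for draw-level resampling.
    """

    nests: tuple[tuple[str, int], ...]
    categories: tuple[str, ...]
    conventional: np.ndarray
    sia_mean: np.ndarray
    posterior: DietPosterior | None = None
    posterior_index: tuple[int, ...] | None = None


def build_paired_table(
    summary: FitSummary,
    conventional: Sequence[DietProportions],
    posterior: DietPosterior | None = None,
    categories: Sequence[str] = CATEGORIES,
) -> PairedDietTable:
    """Align the two methods on shared nest-years (inner join on nest, year)."""
    cats = tuple(categories)
    conv_by_key = {(str(p.nest_id), int(p.year)): p for p in conventional}
    sia = summary.table.pivot_table(
        index=["territory_id", "year"], columns="source", values="mean"
    )
    missing = [c for c in cats if c not in sia.columns]
    if missing:
        raise ValidationError(
            f"category mismatch: comparison categories {missing} absent from the "
            f"mixing-model sources {sorted(sia.columns)}"
        )
    post_key_index: dict[tuple[str, int], int] = {}
    if posterior is not None:
        post_key_index = {
            (str(c.territory_id), int(c.year)): i for i, c in enumerate(posterior.consumers)
        }

    nests, conv_rows, sia_rows, post_idx = [], [], [], []
    for key in sorted(sia.index):
        skey = (str(key[0]), int(key[1]))
        if skey not in conv_by_key:
            logger.info("nest-year %s present only in SIA, excluded from comparison", skey)
            continue
        if posterior is not None and skey not in post_key_index:
            continue
        p = conv_by_key[skey]
        conv_vec = np.array([p.proportions.get(c, 0.0) for c in cats])
        if conv_vec.sum() <= 0:
            raise ValidationError(
                f"category mismatch: conventional proportions for {skey} have no "
                f"mass on comparison categories {cats}"
            )
        conv_vec = conv_vec / conv_vec.sum()
        nests.append(skey)
        conv_rows.append(conv_vec)
        sia_rows.append(np.array([sia.loc[key, c] for c in cats]))
        if posterior is not None:
            post_idx.append(post_key_index[skey])
    if not nests:
        raise ValidationError("no nest-years shared between methods")
    return PairedDietTable(
        nests=tuple(nests),
        categories=cats,
        conventional=np.array(conv_rows),
        sia_mean=np.array(sia_rows),
        posterior=posterior,
        posterior_index=tuple(post_idx) if posterior is not None else None,
    )


def rank_categories(props: Sequence[float]) -> np.ndarray:
    """Rank one nest-year's proportions, 1 = most consumed; ties get average ranks."""
    arr = np.asarray(props, dtype=float)
    if abs(arr.sum() - 1.0) > 1e-6:
        raise ValidationError(f"proportions sum to {arr.sum()}, expected 1")
    return stats.rankdata(-arr, method="average")


def _round_to_half(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float) * 2.0) / 2.0


def weighted_kappa(
    ranks_a: Sequence[float],
    ranks_b: Sequence[float],
    weighting: str = "linear",
    levels: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Weighted Cohen's kappa between two ordinal vectors.

    Kw = 1 - (sum w O) / (sum w E), with disagreement weights w from the
    level-index distance (linear or quadratic) and expected cell
    frequencies E from the marginal products.  The standard error is the
    large-sample null SE (Fleiss-Cohen-Everitt); the p-value is the
    two-sided normal test of Kw against 0.

    Returns (Kw, SE, p).  Degenerate marginals (a single level on both
    sides) yield (nan, nan, nan).
    """
    a = _round_to_half(ranks_a)
    b = _round_to_half(ranks_b)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("rank vectors must have equal length >= 2")
    if weighting not in ("linear", "quadratic"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    if levels is None:
        lv = np.unique(np.concatenate([a, b]))
    else:
        lv = np.asarray(sorted(levels), dtype=float)
    L = len(lv)
    if L < 2:
        return float("nan"), float("nan"), float("nan")
    index = {v: i for i, v in enumerate(lv)}
    try:
        ia = np.array([index[v] for v in a])
        ib = np.array([index[v] for v in b])
    except KeyError as exc:
        raise ValidationError(f"rank value {exc} not on the supplied level grid") from exc

    n = a.size
    O = np.zeros((L, L))
    np.add.at(O, (ia, ib), 1.0)
    O /= n
    pi = O.sum(axis=1)
    qj = O.sum(axis=0)
    E = np.outer(pi, qj)

    d = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :]) / (L - 1)
    w = d if weighting == "linear" else d**2

    wE = float((w * E).sum())
    if wE == 0.0:  # both raters constant
        return float("nan"), float("nan"), float("nan")
    kappa = 1.0 - float((w * O).sum()) / wE

    # Null SE in the agreement-weight formulation v = 1 - w.
    v = 1.0 - w
    pe = float((v * E).sum())
    v_row = v @ qj  # E_j[v_ij] per row level i
    v_col = pi @ v  # E_i[v_ij] per column level j
    term = (E * (v - (v_row[:, None] + v_col[None, :])) ** 2).sum()
    var0 = (term - pe**2) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var0, 0.0)))
    if se == 0.0:
        p = 0.0 if kappa != 0 else 1.0
    else:
        p = 2.0 * stats.norm.sf(abs(kappa) / se)
    return float(kappa), se, float(p)


def icc(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "oneway",
) -> tuple[float, float, float]:
    """Intraclass correlation between two paired measurement vectors.

    ``variant='oneway'`` (default) is the one-way random-effects,
    absolute-agreement, single-rater ICC(1); ``variant='twoway'`` is the
    two-way absolute-agreement ICC(A,1).  Returns (ICC, F, p) with a
    two-sided p from the ANOVA F statistic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("paired vectors must have equal length >= 3")
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    if ss_total == 0.0:
        return float("nan"), float("nan"), float("nan")
    msr = ss_rows / (n - 1)

    if variant == "oneway":
        ss_within = ss_total - ss_rows
        msw = ss_within / (n * (k - 1))
        if msr + msw == 0.0:
            return float("nan"), float("nan"), float("nan")
        value = (msr - msw) / (msr + (k - 1) * msw)
        if msw == 0.0:
            return float(value), float("inf"), 0.0
        f = msr / msw
        dfn, dfd = n - 1, n * (k - 1)
    elif variant == "twoway":
        col_means = x.mean(axis=0)
        ss_cols = n * ((col_means - grand) ** 2).sum()
        ss_err = ss_total - ss_rows - ss_cols
        msc = ss_cols / (k - 1)
        mse = ss_err / ((n - 1) * (k - 1))
        denom = msr + (k - 1) * mse + k / n * (msc - mse)
        if denom == 0.0:
            return float("nan"), float("nan"), float("nan")
        value = (msr - mse) / denom
        if mse == 0.0:
            return float(value), float("inf"), 0.0
        f = msr / mse
        dfn, dfd = n - 1, (n - 1) * (k - 1)
    else:
        raise ValidationError(f"unknown ICC variant {variant!r}")

    cdf = stats.f.cdf(f, dfn, dfd)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(value), float(f), float(p)


def posterior_difference_test(
    paired: PairedDietTable,
    n_draws: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Posterior resampling difference test.

    For each nest-year and category, resample ``n_draws`` posterior
    proportion values (with replacement from the retained MCMC draws,
    seeded) and record the fraction of (conventional - draw) differences
    below zero, i.e. the probability that the mixing-model estimate
    exceeds the conventional one.  Returns (per_nest, summary): per_nest
    has one row per (nest, year, category) with column p_below_0;
    summary has the median and quartiles of those fractions per
    category.
    """
    if paired.posterior is None or paired.posterior_index is None:
        raise ValidationError("paired table has no posterior draws attached")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    name_to_k = {n: i for i, n in enumerate(paired.posterior.source_names)}
    rows = []
    for row, (nest, year) in enumerate(paired.nests):
        flat = paired.posterior.flat(paired.posterior_index[row])  # (draws, K)
        idx = rng.integers(0, flat.shape[0], size=n_draws)
        for j, cat in enumerate(paired.categories):
            draws = flat[idx, name_to_k[cat]]
            frac = float(np.mean(paired.conventional[row, j] - draws < 0.0))
            rows.append({"nest_id": nest, "year": year, "category": cat, "p_below_0": frac})
    per_nest = pd.DataFrame(rows)
    summary = (
        per_nest.groupby("category", sort=False)["p_below_0"]
        .agg(median="median", q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return per_nest, summary


def mean_differences(paired: PairedDietTable) -> pd.DataFrame:
    """Per-category mean (SIA - conventional) difference with its standard error."""
    if len(paired.nests) < 2:
        raise ValidationError("need >= 2 paired nest-years")
    diffs = paired.sia_mean - paired.conventional
    n = diffs.shape[0]
    return pd.DataFrame(
        {
            "category": paired.categories,
            "mean_diff": diffs.mean(axis=0),
            "se_diff": diffs.std(axis=0, ddof=1) / np.sqrt(n),
            "n_nest_years": n,
        }
    )


def category_ranks(matrix: np.ndarray) -> np.ndarray:
    """Within-nest ranks for every row of an (n, 5) proportion matrix."""
    return np.vstack([rank_categories(row) for row in matrix])


def agreement_report(
    paired: PairedDietTable,
    kappa_weighting: str = "linear",
    icc_variant: str = "oneway",
    n_draws: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-category agreement table.

    For each category, the kappa compares that category's within-nest
    consumption rank under each method across nest-years (on the shared
    1-5 half-step grid); the ICC compares the proportion estimates; the
    resampling test summarizes posterior-vs-conventional differences.
    Returns (report, per_nest_p_below_0).
    """
    ranks_conv = category_ranks(paired.conventional)
    ranks_sia = category_ranks(paired.sia_mean)
    per_nest, pdiff_summary = posterior_difference_test(paired, n_draws=n_draws, seed=seed)
    diffs = mean_differences(paired)
    rows = []
    for j, cat in enumerate(paired.categories):
        kw, kw_se, kw_p = weighted_kappa(
            ranks_conv[:, j], ranks_sia[:, j], weighting=kappa_weighting, levels=RANK_GRID
        )
        icc_val, icc_f, icc_p = icc(
            paired.conventional[:, j], paired.sia_mean[:, j], variant=icc_variant
        )
        srow = pdiff_summary[pdiff_summary["category"] == cat].iloc[0]
        drow = diffs[diffs["category"] == cat].iloc[0]
        rows.append(
            {
                "category": cat,
                "kw": kw,
                "kw_se": kw_se,
                "kw_p": kw_p,
                "icc": icc_val,
                "icc_f": icc_f,
                "icc_p": icc_p,
                "median_p_below_0": srow["median"],
                "mean_diff": drow["mean_diff"],
                "se_diff": drow["se_diff"],
            }
        )
    return pd.DataFrame(rows), per_nest
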
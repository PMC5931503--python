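"""CSV / YAML readers and writers for the pipeline's tabular interfaces.

All files are UTF-8, comma-separated, headered, decimal point; missing
values are empty fields.
"""

from __future__ import annotations

from pathlib import Path
from collections.abc import Sequence

import pandas as pd
import yaml

from isodiet.isotope_prep import build_source_spec
from isodiet.types import (
    CategoryCounts,
    ConsumerObservation,
    DietProportions,
    IsotopeSample,
    RemainRecord,
    SourceSpec,
    TEFSpec,
    ValidationError,
)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def read_consumers_csv(path: str | Path) -> list[IsotopeSample]:
    df = pd.read_csv(path)
    _require_columns(df, ["territory_id", "year", "delta13C", "delta15N"], path)
    return [
        IsotopeSample(
            territory_id=str(r.territory_id),
            year=int(r.year),
            delta13C=float(r.delta13C),
            delta15N=float(r.delta15N),
        )
        for r in df.itertuples()
    ]


def write_consumers_csv(samples: Sequence[IsotopeSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "territory_id": s.territory_id,
                "year": s.year,
                "delta13C": s.delta13C,
                "delta15N": s.delta15N,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def read_observations_csv(path: str | Path) -> list[ConsumerObservation]:
    df = pd.read_csv(path)
    _require_columns(
        df, ["territory_id", "year", "mean_delta13C", "mean_delta15N", "n_siblings"], path
    )
    return [
        ConsumerObservation(
            territory_id=str(r.territory_id),
            year=int(r.year),
            mean_delta13C=float(r.mean_delta13C),
            mean_delta15N=float(r.mean_delta15N),
            n_siblings=int(r.n_siblings),
        )
        for r in df.itertuples()
    ]


def write_observations_csv(obs: Sequence[ConsumerObservation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "territory_id": o.territory_id,
                "year": o.year,
                "mean_delta13C": o.mean_delta13C,
                "mean_delta15N": o.mean_delta15N,
                "n_siblings": o.n_siblings,
            }
            for o in obs
        ]
    ).to_csv(path, index=False)


def read_sources_csv(path: str | Path, aggregation: str = "mixture") -> list[SourceSpec]:
    """Read category sources; rows with a ``parent_category`` value are
    per-prey components and are aggregated into their parent category."""
    df = pd.read_csv(path)
    _require_columns(df, ["name", "mu13C", "sd13C", "mu15N", "sd15N"], path)
    has_parent = "parent_category" in df.columns
    out: list[SourceSpec] = []
    if has_parent:
        component_rows = df[df["parent_category"].notna()]
        top_rows = df[df["parent_category"].isna()]
    else:
        component_rows = df.iloc[0:0]
        top_rows = df
    by_parent: dict[str, list[tuple[str, float, float, float, float]]] = {}
    for r in component_rows.itertuples():
        by_parent.setdefault(str(r.parent_category), []).append(
            (str(r.name), float(r.mu13C), float(r.sd13C), float(r.mu15N), float(r.sd15N))
        )
    seen = set()
    for r in top_rows.itertuples():
        name = str(r.name)
        seen.add(name)
        out.append(
            SourceSpec(
                name=name,
                mu13C=float(r.mu13C),
                sd13C=float(r.sd13C),
                mu15N=float(r.mu15N),
                sd15N=float(r.sd15N),
            )
        )
    for parent, comps in by_parent.items():
        if parent in seen:
            raise ValidationError(
                f"{path}: category {parent!r} given both directly and as components"
            )
        out.append(build_source_spec(parent, comps, method=aggregation))
    return out


def write_sources_csv(sources: Sequence[SourceSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "mu13C": s.mu13C,
                "sd13C": s.sd13C,
                "mu15N": s.mu15N,
                "sd15N": s.sd15N,
            }
            for s in sources
        ]
    ).to_csv(path, index=False)


def read_tef(path: str | Path) -> TEFSpec:
    """Read a TEF table from CSV (columns isotope, mu, sd) or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        data = yaml.safe_load(path.read_text())
        return TEFSpec(
            mu13C=float(data["delta13C"]["mu"]),
            sd13C=float(data["delta13C"]["sd"]),
            mu15N=float(data["delta15N"]["mu"]),
            sd15N=float(data["delta15N"]["sd"]),
        )
    df = pd.read_csv(path)
    _require_columns(df, ["isotope", "mu", "sd"], path)
    rows = {str(r.isotope): (float(r.mu), float(r.sd)) for r in df.itertuples()}
    try:
        return TEFSpec(
            mu13C=rows["delta13C"][0],
            sd13C=rows["delta13C"][1],
            mu15N=rows["delta15N"][0],
            sd15N=rows["delta15N"][1],
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing TEF row for isotope {exc}") from exc


def write_tef_csv(tef: TEFSpec, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"isotope": "delta13C", "mu": tef.mu13C, "sd": tef.sd13C},
            {"isotope": "delta15N", "mu": tef.mu15N, "sd": tef.sd15N},
        ]
    ).to_csv(path, index=False)


_REMAINS_COLUMNS = ["nest_id", "year", "taxon", "taxon_group"]


def read_remains_csv(path: str | Path) -> list[RemainRecord]:
    df = pd.read_csv(path)
    _require_columns(df, _REMAINS_COLUMNS, path)

    def opt(row, col, default=None):
        if col not in df.columns:
            return default
        v = getattr(row, col)
        return default if pd.isna(v) else v

    out = []
    for r in df.itertuples():
        out.append(
            RemainRecord(
                nest_id=str(r.nest_id),
                year=int(r.year),
                taxon=str(r.taxon),
                taxon_group=str(r.taxon_group),
                item_kind=str(opt(r, "item_kind", "bone")),
                sampling_moment=str(opt(r, "sampling_moment", "during_breeding")),
                butchery_marks=bool(opt(r, "butchery_marks", False)),
                hair_color=opt(r, "hair_color"),
                hair_length_class=opt(r, "hair_length_class"),
                element=opt(r, "element"),
                side=opt(r, "side"),
                n_elements=int(opt(r, "n_elements", 1)),
                count=int(opt(r, "count", 1)),
            )
        )
    return out


def write_remains_csv(records: Sequence[RemainRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "nest_id": r.nest_id,
                "year": r.year,
                "sampling_moment": r.sampling_moment,
                "taxon": r.taxon,
                "taxon_group": r.taxon_group,
                "item_kind": r.item_kind,
                "element": r.element,
                "side": r.side,
                "butchery_marks": r.butchery_marks,
                "hair_color": r.hair_color,
                "hair_length_class": r.hair_length_class,
                "n_elements": r.n_elements,
                "count": r.count,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_counts_csv(counts: Sequence[CategoryCounts], path: str | Path) -> None:
    rows = []
    for c in counts:
        row = {"nest_id": c.nest_id, "year": c.year}
        row.update(c.counts)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_proportions_csv(props: Sequence[DietProportions], path: str | Path) -> None:
    rows = []
    for p in props:
        row = {"nest_id": p.nest_id, "year": p.year, "others_excluded": p.others_excluded}
        row.update(p.proportions)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_proportions_csv(path: str | Path) -> list[DietProportions]:
    df = pd.read_csv(path)
    _require_columns(df, ["nest_id", "year"], path)
    meta = {"nest_id", "year", "others_excluded"}
    cats = [c for c in df.columns if c not in meta]
    out = []
    for r in df.itertuples():
        out.append(
            DietProportions(
                nest_id=str(r.nest_id),
                year=int(r.year),
                proportions={c: float(getattr(r, c)) for c in cats},
                others_excluded=bool(getattr(r, "others_excluded", False)),
            )
        )
    return out


def write_draws_csv(post, path: str | Path, thin: int = 10) -> None:
    """Long-format posterior draws (thinned) for archival / reanalysis."""
    rows = []
    for i, c in enumerate(post.consumers):
        draws = post.proportions[i, :, ::thin, :]
        n_chains, n_kept, K = draws.shape
        for chain in range(n_chains):
            for it in range(n_kept):
                for k, name in enumerate(post.source_names):
                    rows.append(
                        {
                            "territory_id": c.territory_id,
                            "year": c.year,
                            "chain": chain,
                            "iter": it * thin,
                            "source": name,
                            "value": draws[chain, it, k],
                        }
                    )
    pd.DataFrame(rows).to_csv(path, index=False)
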
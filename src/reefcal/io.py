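"""Read, validate, aggregate and write the tabular survey data.

Two tabular layers flow through the pipeline:

* **point records** — one row per sampled point (site, method, transect,
  point index, label), the raw datum of either survey protocol;
* **cover tables** — one row per site x method x benthic component with a
  percent cover in [0, 100], obtained by dividing the number of point
  records of a component by the number of valid point records.

Percent scale (0-100) is used throughout, matching how reef monitoring
programs report cover.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "POINT_COLUMNS",
    "DEFAULT_COMPONENTS",
    "DEFAULT_EXCLUSIONS",
    "read_point_records",
    "aggregate_cover",
    "pair_methods",
    "validate_cover_table",
    "write_conversion_rules",
    "read_conversion_rules",
]


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """Row content violates a dataset invariant."""


POINT_COLUMNS = (
    "site_id",
    "reef_type",
    "method",
    "transect_id",
    "point_index",
    "label",
)

#: The six broad benthic categories of Caribbean reef monitoring.
DEFAULT_COMPONENTS = (
    "hard_corals",
    "sponges",
    "gorgonians",
    "macroalgae",
    "turf_algae",
    "cca",
)

#: Labels excluded from the valid-point denominator. The field protocols
#: never enumerate these, so the list is configurable; these defaults cover
#: the usual photo/chain annotation artefacts.
DEFAULT_EXCLUSIONS = ("shadow", "tape", "unidentifiable", "other")

METHODS = ("CPI", "PQ")


def read_point_records(
    path: str | Path,
    colmap: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a delimited point-record file into a validated DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row naming the six required columns
        (``site_id, reef_type, method, transect_id, point_index, label``).
    colmap
        Optional mapping from the file's column names to the required
        names, for files using different headers.
    delimiter
        Field delimiter, default comma.

    Returns
    -------
    DataFrame with the six canonical columns.  ``df.attrs`` records the
    row count and distinct sites/methods.

    Raises
    ------
    SchemaError
        if a required column is absent after renaming.
    ValidationError
        if a (site, method, transect, point_index) key is duplicated or a
        label is empty.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"label": str})
    if colmap:
        df = df.rename(columns=dict(colmap))
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(POINT_COLUMNS)].copy()
    df["label"] = df["label"].astype(str).str.strip()
    if (df["label"] == "").any() or df["label"].isna().any():
        bad = df.index[(df["label"] == "") | df["label"].isna()][0]
        raise ValidationError(f"empty label at row {bad}")
    key = ["site_id", "method", "transect_id", "point_index"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].to_dict()
        raise ValidationError(f"duplicate point key {first}")
    df.attrs["n_records"] = len(df)
    df.attrs["sites"] = sorted(df["site_id"].astype(str).unique())
    df.attrs["methods"] = sorted(df["method"].astype(str).unique())
    return df


def aggregate_cover(
    records: pd.DataFrame,
    components: Sequence[str] = DEFAULT_COMPONENTS,
    exclusions: Sequence[str] = DEFAULT_EXCLUSIONS,
    label_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Aggregate point records to percent cover per site x method x component.

    ``cover = 100 * n(component) / n(valid)`` where valid points are those
    whose (mapped) label is in ``components``.  Labels in ``exclusions``
    are dropped from the denominator; unknown labels raise in strict mode
    and are excluded with a warning in lenient mode.

    Returns a tidy CoverTable DataFrame with columns
    ``site_id, reef_type, method, component, cover`` (one row per
    component for every site x method, zeros included).  ``attrs`` carries
    the component list, exclusions used, per-group valid totals and any
    unknown labels seen.
    """
    components = list(components)
    exclusions = list(exclusions)
    df = records.copy()
    if label_map:
        df["label"] = df["label"].map(lambda s: label_map.get(s, s))
    known = set(components) | set(exclusions)
    unknown = sorted(set(df["label"]) - known)
    if unknown:
        if strict:
            raise ValidationError(
                f"unknown label(s) {unknown}; add to components, exclusions "
                "or label_map, or use strict=False"
            )
        import warnings

        warnings.warn(f"excluding unknown label(s): {unknown}", stacklevel=2)
        exclusions = exclusions + unknown

    reef = df.groupby("site_id", observed=True)["reef_type"].agg("unique")
    multi = reef[reef.map(len) > 1]
    if len(multi):
        raise ValidationError(
            f"site(s) with conflicting reef_type: {list(multi.index)}"
        )
    reef_of = reef.map(lambda u: u[0])

    valid = df[df["label"].isin(components)]
    totals = valid.groupby(["site_id", "method"], observed=True).size()
    all_groups = df.groupby(["site_id", "method"], observed=True).size()
    zero = sorted(set(all_groups.index) - set(totals.index))
    if zero:
        raise ValidationError(f"zero valid points for site x method {zero}")

    counts = (
        valid.groupby(["site_id", "method", "label"], observed=True)
        .size()
        .unstack("label", fill_value=0)
        .reindex(columns=components, fill_value=0)
    )
    covers = counts.div(counts.sum(axis=1), axis=0) * 100.0
    out = (
        covers.stack()
        .rename("cover")
        .reset_index()
        .rename(columns={"label": "component"})
    )
    out.insert(1, "reef_type", out["site_id"].map(reef_of))
    out = out[["site_id", "reef_type", "method", "component", "cover"]]
    out.attrs["components"] = components
    out.attrs["exclusions"] = exclusions
    out.attrs["unknown_labels"] = unknown
    out.attrs["valid_totals"] = {k: int(v) for k, v in totals.items()}
    return out


def pair_methods(covers: pd.DataFrame) -> pd.DataFrame:
    """Inner-join the two methods into one paired row per site x component.

    Returns a DataFrame with columns ``site_id, reef_type, component,
    pq_cover, cpi_cover``; ``attrs['n_unpaired']`` counts rows present for
    one method only.  A site whose reef type differs between methods is an
    error.
    """
    need = {"site_id", "reef_type", "method", "component", "cover"}
    missing = need - set(covers.columns)
    if missing:
        raise SchemaError(f"cover table missing column(s): {sorted(missing)}")
    reef = covers.groupby("site_id", observed=True)["reef_type"].nunique()
    if (reef > 1).any():
        raise ValidationError(
            f"conflicting reef_type between methods for site(s) "
            f"{list(reef.index[reef > 1])}"
        )
    wide = covers.pivot_table(
        index=["site_id", "reef_type", "component"],
        columns="method",
        values="cover",
        aggfunc="first",
        observed=True,
    )
    for m in METHODS:
        if m not in wide.columns:
            wide[m] = float("nan")
    paired = wide.dropna(subset=list(METHODS))
    n_unpaired = len(wide) - len(paired)
    if paired.empty:
        import warnings

        warnings.warn("no site x component present under both methods",
                      stacklevel=2)
    out = (
        paired.reset_index()
        .rename(columns={"PQ": "pq_cover", "CPI": "cpi_cover"})
        .loc[:, ["site_id", "reef_type", "component", "pq_cover", "cpi_cover"]]
    )
    out.columns.name = None
    out.attrs["n_unpaired"] = int(n_unpaired)
    return out


def validate_cover_table(covers: pd.DataFrame, tol: float = 0.5) -> dict:
    """Report-only closure and range check on a cover table.

    Returns ``{"closure": [...], "out_of_range": [...]}`` listing
    site x method groups whose component covers do not sum to 100 +/- tol,
    and rows with cover outside [0, 100].
    """
    sums = covers.groupby(["site_id", "method"], observed=True)["cover"].sum()
    closure = [
        {"site_id": s, "method": m, "total": float(t)}
        for (s, m), t in sums.items()
        if abs(t - 100.0) > tol
    ]
    bad = covers[(covers["cover"] < 0) | (covers["cover"] > 100)]
    out_of_range = bad[["site_id", "method", "component", "cover"]].to_dict(
        "records"
    )
    return {"closure": closure, "out_of_range": out_of_range}


def write_conversion_rules(rules: Iterable, path: str | Path) -> None:
    """Serialize conversion rules to JSON (round-trips bit-exactly)."""
    from .conversion import ConversionRule

    payload = [r.to_dict() if isinstance(r, ConversionRule) else dict(r)
               for r in rules]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_conversion_rules(path: str | Path) -> list:
    """Read conversion rules written by :func:`write_conversion_rules`."""
    from .conversion import ConversionRule

    payload = json.loads(Path(path).read_text())
    return [ConversionRule.from_dict(d) for d in payload]
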